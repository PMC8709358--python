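"""Synthetic toy data: ideal α-helix complexes and disorder-profile pairs.

Everything the other modules consume can be generated here with known
ground truth — helix geometries with exact rotations/translations for
superposition and contact tests, and disorder-profile files with injected
per-residue differences for the ΔDI adapter path.  Fixtures are geometric,
not physical: canonical α-helix parameters (2.3 Å radius, 1.5 Å rise and
100° twist per residue), poly-alanine identities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .disorder import DisorderProfile, write_disorder_file
from .errors import SpecError
from .structures import Atom, StructureModel, write_pdb

HELIX_RADIUS = 2.3  # Å, Cα radius of an ideal α-helix
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = math.radians(100.0)  # per residue


@dataclass(frozen=True)
class HelixSpec:
    n_residues: int
    chain: str = "A"
    start: int = 1
    resname: str = "ALA"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    phase: float = 0.0  # radians
    detail: str = "CA"  # CA-only (backbone detail reserved for future use)

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise SpecError("n_residues must be >= 1")
        norm = math.sqrt(sum(c * c for c in self.axis))
        if norm < 1e-9:
            raise SpecError("helix axis must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            object.__setattr__(self, "axis", tuple(c / norm for c in self.axis))


def _frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to *axis* (right-handed frame)."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def make_ideal_helix(spec: HelixSpec) -> np.ndarray:
    """Cα coordinates of an ideal α-helix, one row per residue.

    Residue i sits at angle ``phase + i·100°`` on a 2.3 Å cylinder about
    ``axis`` through ``origin``, offset ``i·1.5 Å`` axially.
    """
    axis = np.asarray(spec.axis)
    origin = np.asarray(spec.origin)
    u, v = _frame(axis)
    i = np.arange(spec.n_residues)
    angles = spec.phase + i * HELIX_TWIST
    coords = (
        origin
        + np.outer(i * HELIX_RISE, axis)
        + HELIX_RADIUS * (np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v))
    )
    return coords


@dataclass(frozen=True)
class ToyComplexSpec:
    helices: tuple[HelixSpec, ...]
    jitter_sigma: float = 0.0  # Å, Gaussian noise on every coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        # helices may share a chain (e.g. two PS1 segments) as long as their
        # residue numberings do not collide
        used: set[tuple[str, int]] = set()
        for h in self.helices:
            span = {(h.chain, h.start + i) for i in range(h.n_residues)}
            if span & used:
                raise SpecError(f"residue numbering collision on chain {h.chain!r}")
            used |= span
        if self.jitter_sigma < 0:
            raise SpecError("jitter_sigma must be >= 0")


def make_toy_complex(spec: ToyComplexSpec, path: str | Path | None = None) -> StructureModel:
    """Assemble helices into one model; optionally write it as a PDB file.

    With ``jitter_sigma > 0`` coordinates get seeded Gaussian noise, bitwise
    reproducible for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    for h in spec.helices:
        coords = make_ideal_helix(h)
        if spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma, coords.shape)
        for i, xyz in enumerate(coords):
            atoms.append(
                Atom(
                    chain=h.chain,
                    resnum=h.start + i,
                    icode="",
                    resname=h.resname,
                    name="CA",
                    element="C",
                    pos=tuple(float(c) for c in xyz),
                )
            )
    model = StructureModel("toy_complex", atoms)
    if path is not None:
        write_pdb(model, path)
    return model


def m1_complex(path: str | Path | None = None, separation: float = 7.0) -> StructureModel:
    """Toy APP/PS1 complex contacting only D1-numbered residues (M1-style).

    Chain P carries a helix numbered over the post-TM6 perimembrane region
    (255–272) and a distant helix numbered over TM7 (370–387); the APP helix
    (chain A, 700–717) runs parallel to the D1 helix at *separation* Å.
    """
    return make_toy_complex(_two_site_spec(contact="d1", separation=separation), path)


def m2_complex(path: str | Path | None = None, separation: float = 7.0) -> StructureModel:
    """Toy complex contacting only D2/TM7-numbered residues (M2-style)."""
    return make_toy_complex(_two_site_spec(contact="d2", separation=separation), path)


def _two_site_spec(contact: str, separation: float) -> ToyComplexSpec:
    d1_x, d2_x = 0.0, 40.0
    app_x = (d1_x if contact == "d1" else d2_x) + separation
    return ToyComplexSpec(
        helices=(
            HelixSpec(n_residues=18, chain="P", start=255, origin=(d1_x, 0.0, 0.0)),
            HelixSpec(n_residues=18, chain="P", start=370, origin=(d2_x, 0.0, 0.0)),
            HelixSpec(n_residues=18, chain="A", start=700, origin=(app_x, 0.0, 0.0)),
        )
    )


def helix_pair(
    separation: float,
    n_residues: int = 18,
    path: str | Path | None = None,
) -> StructureModel:
    """Two parallel poly-Ala helices with axes *separation* Å apart."""
    spec = ToyComplexSpec(
        helices=(
            HelixSpec(n_residues=n_residues, chain="A", start=1),
            HelixSpec(n_residues=n_residues, chain="B", start=1, origin=(separation, 0.0, 0.0)),
        )
    )
    return make_toy_complex(spec, path)


def make_disorder_files(
    base: DisorderProfile,
    edits: Sequence[tuple[int, float]],
    out_dir: str | Path,
    residues: str | None = None,
) -> tuple[Path, Path]:
    """Write a wild-type/edited profile pair in the adapter's column format.

    *edits* are (residue position, new score) replacements; after parsing
    both files back, ``delta_di`` recovers exactly the injected differences
    × 100.  Returns (wild-type path, edited path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = list(base.scores)
    for pos, new in edits:
        idx = pos - base.start
        if not (0 <= idx < len(scores)):
            raise SpecError(f"edit position {pos} outside profile {base.start}-{base.start + len(scores) - 1}")
        if not (0.0 <= new <= 1.0):
            raise SpecError(f"edited score {new} outside [0, 1]")
        scores[idx] = new
    edited = replace(base, scores=tuple(scores), source="external", params_or_file=None)
    base_ext = replace(base, source="external", params_or_file=None)
    wt_path = out_dir / "wildtype.diso"
    mut_path = out_dir / "edited.diso"
    write_disorder_file(base_ext, wt_path, residues=residues)
    write_disorder_file(edited, mut_path, residues=residues)
    return wt_path, mut_path
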