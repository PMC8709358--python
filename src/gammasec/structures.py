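"""Coordinate handling for γ-secretase conformer analysis.

Solved γ-secretase structures superpose well over the presenilin-1
C-terminal fragment (TM7–TM9) while the N-terminal fragment — TM6 in
particular — swings between conformations.  This module parses deposited
coordinates, superposes conformers on the TM7–TM9 anchor (Kabsch
least-squares), quantifies per-residue Cα displacement of a probe region
such as TM6, computes inter-chain residue contact maps, and classifies an
APP/presenilin complex as M1-like (APP contacting the post-TM6
perimembrane region, D1) or M2-like (APP contacting TM7, D2).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ChainError,
    ConfigurationError,
    EmptyModelError,
    RegionError,
    SelectionError,
    StructureFormatError,
)

ResidueKey = tuple[int, str]  # (residue number, insertion code)

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    pos: tuple[float, float, float]

    @property
    def reskey(self) -> ResidueKey:
        return (self.resnum, self.icode)


class StructureModel:
    """An immutable list of heavy atoms with a per-chain residue index."""

    def __init__(self, source_id: str, atoms: Sequence[Atom]):
        if not atoms:
            raise EmptyModelError(f"structure {source_id!r} has no usable atoms")
        seen: set[tuple[str, ResidueKey, str]] = set()
        for a in atoms:
            key = (a.chain, a.reskey, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom after altloc filtering: {key}")
            if not all(np.isfinite(a.pos)):
                raise ValueError(f"non-finite coordinate on atom {key}")
            seen.add(key)
        self.source_id = source_id
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        index: dict[str, dict[ResidueKey, list[Atom]]] = {}
        for a in self.atoms:
            index.setdefault(a.chain, {}).setdefault(a.reskey, []).append(a)
        self._index = index

    @property
    def chains(self) -> tuple[str, ...]:
        return tuple(self._index)

    def __len__(self) -> int:
        return len(self.atoms)

    def chain_residues(self, chain: str) -> dict[ResidueKey, list[Atom]]:
        try:
            return self._index[chain]
        except KeyError:
            raise ChainError(f"chain {chain!r} not in structure (have {list(self._index)})") from None

    def ca_map(self, chain: str, start: int | None = None, end: int | None = None
               ) -> dict[ResidueKey, np.ndarray]:
        """Cα coordinates keyed by residue, optionally limited to a range."""
        out = {}
        for key, atoms in self.chain_residues(chain).items():
            if start is not None and not (start <= key[0] <= end):
                continue
            for a in atoms:
                if a.name == "CA":
                    out[key] = np.asarray(a.pos)
                    break
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped through x -> R x + t."""
        R = np.asarray(rotation)
        t = np.asarray(translation)
        atoms = [replace(a, pos=tuple(R @ np.asarray(a.pos) + t)) for a in self.atoms]
        return StructureModel(self.source_id, atoms)


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read PDB or mmCIF coordinates into a :class:`StructureModel`.

    Hydrogens and waters are dropped; for alternate locations only the
    first-listed conformer of each atom is kept; deposited residue numbering
    and insertion codes are preserved verbatim.  Only the first model of
    multi-model files is used.
    """
    path = Path(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format.lower())
    if fmt is None:
        raise ValueError(f"format must be pdb, mmcif or auto, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"structure {path} has no models")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            taken: set[str] = set()
            for atom in residue:
                if atom.element == gemmi.Element("H") or atom.element == gemmi.Element("D"):
                    continue
                if atom.name in taken:  # later altloc of an already-seen atom
                    continue
                taken.add(atom.name)
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        resname=residue.name,
                        name=atom.name,
                        element=atom.element.name,
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    if not atoms:
        raise EmptyModelError(f"structure {path} contains no non-water heavy atoms")
    return StructureModel(path.stem, atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write minimal compliant ATOM records (occupancy 1.00, B 0.00)."""
    with open(path, "w") as fh:
        serial = 0
        for a in model.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.pos
            fh.write(
                f"ATOM  {serial:5d} {name:<4s}{'':1s}{a.resname:<3s} {a.chain:1s}"
                f"{a.resnum:4d}{a.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Region specification
# ---------------------------------------------------------------------------

Range = tuple[int, int]


@dataclass(frozen=True)
class RegionSpec:
    """Named residue ranges on the PS1 and APP chains (UniProt numbering).

    TM boundaries are editable defaults; ``app_numbering_offset`` handles
    deposited APP chains numbered in Aβ convention: structure residue number
    = UniProt number − offset, so offset 671 maps Aβ residue 1 onto APP D672.
    """

    ps1_chain: str = "P"
    app_chain: str = "A"
    d1: Range = (251, 286)
    d2: Range = (364, 400)
    tm6: Range = (244, 264)
    tm7: Range = (381, 401)
    tm8: Range = (407, 429)
    tm9: Range = (433, 453)
    app_tm: Range = (700, 723)
    viat: Range = (711, 714)
    catalytic_asp: tuple[int, int] = (257, 385)
    app_numbering_offset: int = 0

    def __post_init__(self) -> None:
        for label in ("d1", "d2", "tm6", "tm7", "tm8", "tm9", "app_tm", "viat"):
            lo, hi = getattr(self, label)
            if lo > hi:
                raise ConfigurationError(f"region {label} range not well-ordered: {lo}-{hi}")
        if self.viat[1] - self.viat[0] + 1 != 4:
            raise ConfigurationError(f"viat range must span 4 residues, got {self.viat}")

    @property
    def ct_anchor(self) -> tuple[Range, ...]:
        """TM7–TM9: the superposition anchor shared by all solved conformers."""
        return (self.tm7, self.tm8, self.tm9)

    def app_position(self, uniprot_position: int) -> int:
        """UniProt APP number -> residue number as deposited on the APP chain."""
        return uniprot_position - self.app_numbering_offset

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionSpec":
        """Read ``key = chain:start-end`` lines (``#`` comments allowed).

        Range keys: d1, d2, tm6..tm9, app_tm, viat (chain part sets the PS1
        or APP chain id); scalar keys: app_offset, catalytic_asp (= two
        comma-separated positions, no chain part).
        """
        kwargs: dict[str, object] = {}
        ps1_keys = {"d1", "d2", "tm6", "tm7", "tm8", "tm9"}
        app_keys = {"app_tm", "viat"}
        for lineno, raw in enumerate(open(path), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, value = (s.strip() for s in line.split("=", 1))
            except ValueError:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'") from None
            if key in ps1_keys | app_keys:
                chain, span = value.split(":")
                lo, hi = (int(v) for v in span.split("-"))
                kwargs[key] = (lo, hi)
                kwargs["ps1_chain" if key in ps1_keys else "app_chain"] = chain.strip()
            elif key == "app_offset":
                kwargs["app_numbering_offset"] = int(value)
            elif key == "catalytic_asp":
                a, b = (int(v) for v in value.split(","))
                kwargs["catalytic_asp"] = (a, b)
            else:
                raise ConfigurationError(f"{path}:{lineno}: unknown region key {key!r}")
        return cls(**kwargs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, applied to the moving model
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_atoms: int
    selection: str
    rank_warning: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def to_text(self) -> str:
        """3×4 [R | t] matrix block."""
        rows = [
            " ".join(f"{v:12.6f}" for v in (*self.rotation[i], self.translation[i]))
            for i in range(3)
        ]
        return "\n".join(rows) + "\n"


def _kabsch(mov: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Least-squares rotation/translation mapping mov onto ref.

    Returns (R, t, rank_warning) with rank_warning set when the point cloud
    is degenerate (collinear or coincident) and the rotation is not unique.
    """
    mc, rc = mov.mean(axis=0), ref.mean(axis=0)
    H = (mov - mc).T @ (ref - rc)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0
    R = Vt.T @ np.diag([1.0, 1.0, sign]) @ U.T
    t = rc - R @ mc
    scale = S[0] if S[0] > 0 else 1.0
    rank_warning = bool(S[1] / scale < 1e-8)
    return R, t, rank_warning


def _paired_ca(ref: StructureModel, mov: StructureModel, chain: str,
               ranges: Iterable[Range]) -> tuple[np.ndarray, np.ndarray, int]:
    ref_ca, mov_ca = {}, {}
    for lo, hi in ranges:
        ref_ca.update(ref.ca_map(chain, lo, hi))
        mov_ca.update(mov.ca_map(chain, lo, hi))
    common = sorted(set(ref_ca) & set(mov_ca))
    if len(common) < 3:
        raise SelectionError(
            f"selection resolves to only {len(common)} common Cα atoms (need >= 3)"
        )
    R = np.array([ref_ca[k] for k in common])
    M = np.array([mov_ca[k] for k in common])
    return R, M, len(common)


def superpose(
    ref: StructureModel,
    mov: StructureModel,
    selection: Iterable[Range] | RegionSpec,
    chain: str | None = None,
) -> SuperpositionResult:
    """Rigid least-squares superposition of *mov* onto *ref*.

    *selection* is a set of inclusive residue ranges (or a
    :class:`RegionSpec`, whose TM7–TM9 anchor is used) on *chain*
    (default: the RegionSpec's PS1 chain, else the first chain of *ref*);
    Cα atoms are paired by residue number and insertion code.
    """
    if isinstance(selection, RegionSpec):
        ranges: tuple[Range, ...] = selection.ct_anchor
        chain = chain or selection.ps1_chain
    else:
        ranges = tuple(selection)
        chain = chain or ref.chains[0]
    ref_xyz, mov_xyz, n = _paired_ca(ref, mov, chain, ranges)
    R, t, rank_warning = _kabsch(mov_xyz, ref_xyz)
    moved = mov_xyz @ R.T + t
    rmsd = float(np.sqrt(((moved - ref_xyz) ** 2).sum(axis=1).mean()))
    desc = f"chain {chain} Cα " + ",".join(f"{lo}-{hi}" for lo, hi in ranges)
    return SuperpositionResult(R, t, rmsd, n, desc, rank_warning)


@dataclass(frozen=True)
class DisplacementProfile:
    probe: str
    entries: tuple[tuple[int, float], ...]  # (residue number, Cα displacement Å)
    absent: tuple[int, ...]  # probe residues unresolved in either model

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\tdisplacement_A\n")
            for resnum, d in self.entries:
                fh.write(f"{resnum}\t{d:.4f}\n")


def per_residue_displacement(
    ref: StructureModel,
    mov: StructureModel,
    transform: SuperpositionResult,
    probe: Range,
    chain: str | None = None,
) -> DisplacementProfile:
    """Cα displacement of each probe residue after applying *transform* to *mov*.

    Residues missing a Cα in either model are listed as absent rather than
    raising.
    """
    chain = chain or ref.chains[0]
    lo, hi = probe
    ref_ca = ref.ca_map(chain, lo, hi)
    mov_ca = mov.ca_map(chain, lo, hi)
    entries, absent = [], []
    for resnum in range(lo, hi + 1):
        keys = [k for k in set(ref_ca) & set(mov_ca) if k[0] == resnum]
        if not keys:
            if any(k[0] == resnum for k in set(ref_ca) | set(mov_ca)):
                absent.append(resnum)
            continue
        for k in sorted(keys):
            moved = transform.apply(mov_ca[k])
            entries.append((resnum, float(np.linalg.norm(moved - ref_ca[k]))))
    return DisplacementProfile(
        probe=f"chain {chain} {lo}-{hi}", entries=tuple(entries), absent=tuple(absent)
    )


# ---------------------------------------------------------------------------
# Contacts and conformation calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactMap:
    chain_a: str
    chain_b: str
    cutoff: float
    pairs: tuple[tuple[ResidueKey, ResidueKey, float], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[tuple[ResidueKey, ResidueKey]]:
        return {(a, b) for a, b, _ in self.pairs}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"res_{self.chain_a}\tres_{self.chain_b}\tmin_distance_A\n")
            for (na, ia), (nb, ib), d in self.pairs:
                fh.write(f"{na}{ia}\t{nb}{ib}\t{d:.3f}\n")


def contact_map(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 4.5
) -> ContactMap:
    """Inter-chain residue pairs whose minimum heavy-atom distance ≤ cutoff.

    4.5 Å is the conventional van der Waals contact criterion.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    res_a = model.chain_residues(chain_a)
    res_b = model.chain_residues(chain_b)

    atoms_a = [(key, np.asarray(a.pos)) for key, atoms in res_a.items() for a in atoms]
    atoms_b = [(key, np.asarray(a.pos)) for key, atoms in res_b.items() for a in atoms]
    xyz_a = np.array([p for _, p in atoms_a])
    xyz_b = np.array([p for _, p in atoms_b])

    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    tree_b = cKDTree(xyz_b)
    for ia, neighbors in enumerate(cKDTree(xyz_a).query_ball_tree(tree_b, cutoff)):
        if not neighbors:
            continue
        key_a = atoms_a[ia][0]
        dists = np.linalg.norm(xyz_b[neighbors] - xyz_a[ia], axis=1)
        for ib, d in zip(neighbors, dists):
            if d <= cutoff:
                pair = (key_a, atoms_b[ib][0])
                if d < best.get(pair, np.inf):
                    best[pair] = float(d)
    pairs = tuple(sorted((a, b, best[(a, b)]) for a, b in best))
    return ContactMap(chain_a, chain_b, float(cutoff), pairs)


@dataclass(frozen=True)
class ConformationCall:
    m1_score: float  # fraction of APP contacts on the D1 (post-TM6) region
    m2_score: float  # fraction on the D2 (TM7) region
    call: str  # M1 | M2 | ambiguous
    margin: float
    n_contacts: int


def classify_conformation(
    cm: ContactMap, regions: RegionSpec, margin: float = 0.1
) -> ConformationCall:
    """Call a complex M1-like or M2-like from its APP–PS1 contact map.

    The score of each conformation is the fraction of contact pairs whose
    PS1 residue falls in its diagnostic region (D1 for M1, D2 for M2); the
    call requires a score gap larger than *margin*, else ambiguous.
    """
    d1, d2 = regions.d1, regions.d2
    if not (d1[1] < d2[0] or d2[1] < d1[0]):
        raise ConfigurationError(f"D1 {d1} and D2 {d2} ranges overlap")
    if regions.ps1_chain == cm.chain_b:
        ps1_side = 1
    elif regions.ps1_chain == cm.chain_a:
        ps1_side = 0
    else:
        raise ChainError(
            f"PS1 chain {regions.ps1_chain!r} is neither side of the contact map "
            f"({cm.chain_a!r}, {cm.chain_b!r})"
        )
    total = len(cm.pairs)
    if total == 0:
        return ConformationCall(0.0, 0.0, "ambiguous", margin, 0)
    n_d1 = n_d2 = 0
    for pair in cm.pairs:
        resnum = pair[ps1_side][0]
        if d1[0] <= resnum <= d1[1]:
            n_d1 += 1
        elif d2[0] <= resnum <= d2[1]:
            n_d2 += 1
    m1, m2 = n_d1 / total, n_d2 / total
    if m1 - m2 > margin:
        call = "M1"
    elif m2 - m1 > margin:
        call = "M2"
    else:
        call = "ambiguous"
    return ConformationCall(m1, m2, call, margin, total)


@dataclass(frozen=True)
class CatalyticDistances:
    d_viat_asp1: float  # min heavy-atom distance VIAT -> first catalytic Asp, Å
    d_viat_asp2: float
    asp1_ca_fallback: bool  # True when the Asp side chain is unmodeled
    asp2_ca_fallback: bool


def catalytic_distances(model: StructureModel, regions: RegionSpec) -> CatalyticDistances:
    """Minimum distances from the VIAT stretch of APP to each catalytic Asp.

    Uses the aspartate side-chain atoms, falling back to Cα (flagged) when
    only the backbone is modeled.
    """
    lo, hi = regions.viat
    app_res = model.chain_residues(regions.app_chain)
    viat_xyz = [
        np.asarray(a.pos)
        for key, atoms in app_res.items()
        if regions.app_position(lo) <= key[0] <= regions.app_position(hi)
        for a in atoms
    ]
    if not viat_xyz:
        raise RegionError(
            f"VIAT range {regions.viat} (chain numbering "
            f"{regions.app_position(lo)}-{regions.app_position(hi)}) "
            f"does not resolve on chain {regions.app_chain!r}"
        )
    viat_xyz = np.array(viat_xyz)

    ps1_res = model.chain_residues(regions.ps1_chain)
    results, fallbacks = [], []
    for asp_pos in regions.catalytic_asp:
        atoms = [a for key, group in ps1_res.items() if key[0] == asp_pos for a in group]
        if not atoms:
            raise RegionError(
                f"catalytic aspartate {asp_pos} does not resolve on chain "
                f"{regions.ps1_chain!r}"
            )
        side = [a for a in atoms if a.name not in _BACKBONE]
        fallback = not side
        if fallback:
            side = [a for a in atoms if a.name == "CA"]
            if not side:
                raise RegionError(f"aspartate {asp_pos} has neither side chain nor Cα")
        xyz = np.array([a.pos for a in side])
        dmin = float(np.sqrt(((viat_xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)).min())
        results.append(dmin)
        fallbacks.append(fallback)
    return CatalyticDistances(results[0], results[1], fallbacks[0], fallbacks[1])
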