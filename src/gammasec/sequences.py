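"""Sequence windows, familial-AD mutation catalogs, and point substitutions.

The package ships three UniProt-numbered windows — the APP fragment from the
β-secretase cleavage site through the end of the transmembrane helix
(M671–S730), and the two presenilin-1 regions flanking the catalytic
aspartates, D1 (A251–L286, TM6 + perimembrane) and D2 (L364–A400, TM7
vicinity) — together with the published familial Alzheimer's disease (FAD)
missense substitutions that fall inside them.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .errors import PositionRangeError, UnknownCatalogError, WildtypeMismatchError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceWindow:
    """A contiguous residue window in 1-based UniProt numbering.

    ``regions`` carries inclusive (label, start, end) annotations such as the
    transmembrane span; they are metadata and never enter any computation.
    """

    id: str
    start: int
    residues: str
    regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid letters in window {self.id!r}: {sorted(bad)}")
        if not self.residues:
            raise ValueError("empty sequence window")
        for label, lo, hi in self.regions:
            if not (self.start <= lo <= hi <= self.end):
                raise ValueError(f"region {label!r} ({lo}-{hi}) outside window {self.start}-{self.end}")

    @property
    def end(self) -> int:
        return self.start + len(self.residues) - 1

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def offset(self, position: int) -> int:
        """0-based index of a UniProt position within the window."""
        if position not in self:
            raise PositionRangeError(
                f"position {position} outside window {self.id} ({self.start}-{self.end})"
            )
        return position - self.start

    def residue_at(self, position: int) -> str:
        return self.residues[self.offset(position)]

    def to_fasta(self) -> str:
        return f">{self.id}/{self.start}-{self.end}\n{self.residues}\n"

    @classmethod
    def from_fasta(cls, text: str) -> "SequenceWindow":
        lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
        if not lines or not lines[0].startswith(">"):
            raise ValueError("not FASTA: missing '>' header")
        header = lines[0][1:]
        try:
            wid, span = header.rsplit("/", 1)
            start, _ = span.split("-")
        except ValueError as exc:
            raise ValueError(f"FASTA header {header!r} is not 'id/start-end'") from exc
        return cls(id=wid, start=int(start), residues="".join(lines[1:]))


@dataclass(frozen=True)
class Mutation:
    """A single-residue substitution in UniProt numbering."""

    position: int
    wt: str
    mut: str
    label: str = ""

    def __post_init__(self) -> None:
        for letter in (self.wt, self.mut):
            if letter not in AMINO_ACIDS:
                raise ValueError(f"invalid amino-acid letter {letter!r}")
        if self.wt == self.mut:
            raise ValueError(f"silent substitution {self.wt}{self.position}{self.mut}")

    @property
    def name(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def parse(cls, name: str, label: str = "") -> "Mutation":
        """Parse compact notation like ``'V717F'``."""
        return cls(position=int(name[1:-1]), wt=name[0], mut=name[-1], label=label)


@dataclass(frozen=True)
class MutationCatalog:
    name: str
    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        seen = set()
        for m in self.mutations:
            key = (m.position, m.mut)
            if key in seen:
                raise ValueError(f"duplicate substitution {m.name} in catalog {self.name}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[Mutation]:
        return iter(self.mutations)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["position", "wt", "mut", "label"])
            for m in self.mutations:
                w.writerow([m.position, m.wt, m.mut, m.label])

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "MutationCatalog":
        path = Path(path)
        muts = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                muts.append(
                    Mutation(int(row["position"]), row["wt"], row["mut"], row.get("label", ""))
                )
        return cls(name or path.stem, tuple(muts))


# ---------------------------------------------------------------------------
# Shipped windows.  APP M671-S730 starts at the β-secretase cleavage site and
# runs through the transmembrane helix; PS1 D1/D2 bracket the catalytic
# aspartates D257 and D385.
# ---------------------------------------------------------------------------

APP_WINDOW = SequenceWindow(
    id="APP",
    start=671,
    residues="MDAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIATVIVITLVMLKKKQYTS",
    regions=(("TM", 700, 723), ("FAD_mutated", 705, 723), ("alpha_helix_model", 671, 730)),
)

PS1_D1_WINDOW = SequenceWindow(
    id="PS1_D1",
    start=251,
    residues="AVISVYDLVAVLCPKGPLRMLVETAQERNETLFPAL",
    regions=(("TM6_part", 251, 264), ("catalytic_D257", 257, 257), ("endoproteolysis", 286, 286)),
)

PS1_D2_WINDOW = SequenceWindow(
    id="PS1_D2",
    start=364,
    residues="LSSSILAGEDPEERGVKLGLGDFIFYSVLVGKASATA",
    regions=(("TM7_part", 381, 400), ("catalytic_D385", 385, 385)),
)

WINDOWS: dict[str, SequenceWindow] = {
    "APP": APP_WINDOW,
    "PS1_D1": PS1_D1_WINDOW,
    "PS1_D2": PS1_D2_WINDOW,
}

_APP_TM_NAMES = [
    ("L705V", ""),
    ("A713V", ""),
    ("T714A", "Iranian"),
    ("T714I", "Austrian"),
    ("V715M", "French"),
    ("V715A", "German"),
    ("I716V", "Florida"),
    ("I716F", "Iberian"),
    ("V717F", "Indiana"),
    ("V717I", "London"),
    ("T719N", ""),
    ("T719P", ""),
    ("M722K", ""),
    ("L723P", "Australian"),
]

_PS1_D1_NAMES = [
    "Y256F", "A260V", "V261F", "L262F", "C263F", "P264L", "G266S", "P267T",
    "R269H", "L271V", "E273A", "T274R", "A275V", "R278T", "E280A", "L282V",
    "A285V",
]

# Printed order (not position-sorted).
_PS1_D2_NAMES = [
    "S365Y", "L381F", "Y389F", "R377M", "G378V", "G384A", "F386S", "S390I",
    "V391F", "L392V", "G394V", "A396T",
]

CATALOGS: dict[str, MutationCatalog] = {
    "APP_TM": MutationCatalog(
        "APP_TM", tuple(Mutation.parse(n, label) for n, label in _APP_TM_NAMES)
    ),
    "PS1_D1": MutationCatalog("PS1_D1", tuple(Mutation.parse(n) for n in _PS1_D1_NAMES)),
    "PS1_D2": MutationCatalog("PS1_D2", tuple(Mutation.parse(n) for n in _PS1_D2_NAMES)),
}

#: window shipped alongside each catalog
CATALOG_WINDOWS: dict[str, str] = {"APP_TM": "APP", "PS1_D1": "PS1_D1", "PS1_D2": "PS1_D2"}


def load_window(name: str) -> SequenceWindow:
    try:
        return WINDOWS[name]
    except KeyError:
        raise UnknownCatalogError(f"no such window: {name!r} (have {sorted(WINDOWS)})") from None


def load_catalog(name: str) -> MutationCatalog:
    try:
        return CATALOGS[name]
    except KeyError:
        raise UnknownCatalogError(
            f"no such catalog: {name!r} (have {sorted(CATALOGS)})"
        ) from None


def apply_mutation(window: SequenceWindow, m: Mutation) -> SequenceWindow:
    """Return a copy of *window* with the single substitution applied.

    Raises :class:`PositionRangeError` if the position is outside the window
    and :class:`WildtypeMismatchError` if the declared wild-type residue does
    not match the window sequence.
    """
    i = window.offset(m.position)  # raises PositionRangeError
    found = window.residues[i]
    if found != m.wt:
        raise WildtypeMismatchError(
            f"position {m.position}: expected wild-type {m.wt!r}, window has {found!r}"
        )
    mutated = window.residues[:i] + m.mut + window.residues[i + 1 :]
    return replace(window, residues=mutated)


@dataclass(frozen=True)
class ValidationEntry:
    mutation: Mutation
    position_ok: bool
    wt_ok: bool

    @property
    def ok(self) -> bool:
        return self.position_ok and self.wt_ok


@dataclass(frozen=True)
class ValidationReport:
    catalog_name: str
    window_id: str
    entries: tuple[ValidationEntry, ...]

    @property
    def n_pass(self) -> int:
        return sum(e.ok for e in self.entries)

    @property
    def all_ok(self) -> bool:
        return all(e.ok for e in self.entries)

    def __str__(self) -> str:
        lines = [f"catalog {self.catalog_name} vs window {self.window_id}: "
                 f"{self.n_pass}/{len(self.entries)} pass"]
        for e in self.entries:
            if not e.ok:
                why = "position" if not e.position_ok else "wild-type"
                lines.append(f"  FAIL {e.mutation.name}: {why} check")
        return "\n".join(lines)


def validate_catalog(catalog: MutationCatalog, window: SequenceWindow) -> ValidationReport:
    """Check every catalog entry against the window; failures are report rows."""
    entries = []
    for m in catalog:
        pos_ok = m.position in window
        wt_ok = pos_ok and window.residue_at(m.position) == m.wt
        entries.append(ValidationEntry(m, pos_ok, wt_ok))
    return ValidationReport(catalog.name, window.id, tuple(entries))
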