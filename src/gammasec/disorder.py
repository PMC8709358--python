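"""Per-residue disorder profiles.

Two sources are supported:

* a built-in closed-form scorer in the FoldIndex tradition — a sliding-window
  balance of mean Kyte–Doolittle hydropathy against mean net charge, mapped
  through a logistic so scores land in [0, 1] with high = disordered.  It is
  a transparent, fully reproducible stand-in for trained disorder predictors
  and makes the whole ΔDI pipeline executable offline;
* an adapter for externally generated DISOPRED-style column files
  (``index residue mark probability``), so profiles produced by a trained
  predictor can be dropped into the same pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DisorderParseError
from .sequences import SequenceWindow

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Side-chain formal charge at neutral pH; histidine treated as neutral,
#: termini uncharged.
DEFAULT_CHARGE: Mapping[str, float] = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


@dataclass(frozen=True)
class ScorerParams:
    """Parameters of the built-in scorer.

    The fold index at position *i* over its (edge-truncated) window is

        I_i = coeff_h * <H> - |<q>| - coeff_c

    with <H> the mean hydropathy normalised to [0, 1] via (KD + 4.5)/9 and
    <q> the mean charge; the disorder score is the logistic
    1 / (1 + exp(steepness * I_i)), so positive fold index (hydrophobic,
    uncharged) means ordered.  The default steepness 5.0 maps |I| = 1 to
    scores of about 0.007 / 0.993.
    """

    window_width: int = 11
    steepness: float = 5.0
    hydropathy_scale: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    charge_map: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CHARGE))
    coeff_h: float = 2.785
    coeff_c: float = 1.151

    def __post_init__(self) -> None:
        if self.window_width < 3 or self.window_width % 2 == 0:
            raise ConfigurationError(f"window_width must be odd and >= 3, got {self.window_width}")
        if self.steepness <= 0:
            raise ConfigurationError("steepness must be positive")
        missing = set(KYTE_DOOLITTLE) - set(self.hydropathy_scale)
        if missing:
            raise ConfigurationError(f"hydropathy scale missing residues: {sorted(missing)}")


@dataclass(frozen=True)
class DisorderProfile:
    """Ordered per-residue disorder scores in [0, 1] for one window."""

    window_id: str
    start: int
    scores: tuple[float, ...]
    source: str = "builtin"  # builtin | external
    params_or_file: object = None

    def __post_init__(self) -> None:
        for s in self.scores:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"disorder score {s} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)


def score_profile(window: SequenceWindow, params: ScorerParams | None = None) -> DisorderProfile:
    """Score every residue of *window* with the built-in scorer.

    Windows truncate (shrink) at the sequence ends rather than padding with
    invented flanking residues.
    """
    params = params or ScorerParams()
    seq = window.residues
    try:
        hyd = np.array([(params.hydropathy_scale[a] + 4.5) / 9.0 for a in seq])
    except KeyError as exc:
        raise ConfigurationError(f"residue {exc.args[0]!r} missing from hydropathy scale") from None
    chg = np.array([params.charge_map.get(a, 0.0) for a in seq])

    half = params.window_width // 2
    n = len(seq)
    scores = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        mean_h = hyd[lo:hi].mean()
        mean_q = chg[lo:hi].mean()
        fold_index = params.coeff_h * mean_h - abs(mean_q) - params.coeff_c
        scores.append(1.0 / (1.0 + math.exp(params.steepness * fold_index)))
    return DisorderProfile(
        window_id=window.id,
        start=window.start,
        scores=tuple(scores),
        source="builtin",
        params_or_file=params,
    )


def parse_disorder_file(path: str | Path) -> DisorderProfile:
    """Parse a DISOPRED-style column file into a profile.

    Lines are ``index residue mark probability`` with mark ``*`` (disordered)
    or ``.`` (ordered); ``#`` comment lines are skipped.  Indices must be
    consecutive; the first index becomes the profile start.
    """
    path = Path(path)
    scores: list[float] = []
    start: int | None = None
    expected: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise DisorderParseError(f"expected 4 columns, got {len(parts)}", lineno)
            idx_s, residue, mark, prob_s = parts
            try:
                idx = int(idx_s)
                prob = float(prob_s)
            except ValueError:
                raise DisorderParseError(f"malformed record {line!r}", lineno) from None
            if mark not in {"*", "."}:
                raise DisorderParseError(f"mark must be '*' or '.', got {mark!r}", lineno)
            if not (0.0 <= prob <= 1.0):
                raise DisorderParseError(f"probability {prob} outside [0, 1]", lineno)
            if expected is None:
                start = idx
            elif idx != expected:
                raise DisorderParseError(f"non-consecutive index {idx}, expected {expected}", lineno)
            expected = idx + 1
            scores.append(prob)
    if not scores:
        raise DisorderParseError("no records")
    return DisorderProfile(
        window_id=path.stem,
        start=start,  # type: ignore[arg-type]
        scores=tuple(scores),
        source="external",
        params_or_file=str(path),
    )


def write_disorder_file(
    profile: DisorderProfile,
    path: str | Path,
    residues: str | None = None,
    threshold: float = 0.5,
) -> None:
    """Write a profile in the same column dialect the parser reads.

    Probabilities are printed with 6 decimals, so profiles whose scores are
    exact at that precision round-trip bit-exactly.
    """
    if residues is not None and len(residues) != len(profile):
        raise ValueError("residues string length must match profile length")
    with open(path, "w") as fh:
        fh.write(f"# disorder profile {profile.window_id} start={profile.start}\n")
        for i, s in enumerate(profile.scores):
            aa = residues[i] if residues else "X"
            mark = "*" if s >= threshold else "."
            fh.write(f"{profile.start + i:5d} {aa} {mark} {s:.6f}\n")
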