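"""Mutational ΔDI scanning.

For each catalogued substitution the wild-type and mutant windows are scored,
the per-residue difference (mutant − wild-type, positive = more disordered)
is taken, and two scalars are reported on a ×100 scale: ``ddi_sum`` (summed
probability change, the primary statistic) and ``ddi_peak`` (largest absolute
single-residue change).  Sign-pattern summaries surface the majority
direction per region and the minority-sign "exception" mutations.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .disorder import DisorderProfile, ScorerParams, score_profile
from .errors import AlignmentError, EmptyInputError
from .sequences import Mutation, MutationCatalog, SequenceWindow, apply_mutation, validate_catalog

#: |ddi_sum| below this counts as sign "zero" (ddi_sum is on the ×100 scale).
ZERO_TOL = 1e-9

ScorerFn = Callable[[SequenceWindow], DisorderProfile]


@dataclass(frozen=True)
class DeltaDIResult:
    mutation: Mutation | None
    delta_profile: tuple[float, ...]
    ddi_sum: float
    ddi_peak: float
    sign: str  # positive | negative | zero


@dataclass(frozen=True)
class SignSummary:
    n_positive: int
    n_negative: int
    n_zero: int
    majority: str  # positive | negative | zero | "no majority"
    exceptions: tuple[str, ...]  # names of minority-sign mutations


@dataclass(frozen=True)
class ScanTable:
    catalog_name: str
    scorer: str
    rows: tuple[DeltaDIResult, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            m = r.mutation
            recs.append(
                dict(
                    label=(m.label or m.name) if m else "",
                    position=m.position if m else None,
                    wt=m.wt if m else "",
                    mut=m.mut if m else "",
                    ddi_sum=r.ddi_sum,
                    ddi_peak=r.ddi_peak,
                    sign=r.sign,
                )
            )
        return pd.DataFrame.from_records(
            recs, columns=["label", "position", "wt", "mut", "ddi_sum", "ddi_peak", "sign"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def summary_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# ΔDI scan: catalog {self.catalog_name}, scorer {self.scorer}\n")
        buf.write(f"# {len(self.rows)} mutations\n")
        if self.rows:
            s = summarize_signs(self)
            buf.write(
                f"# signs: {s.n_positive} positive, {s.n_negative} negative, {s.n_zero} zero"
                f" -> majority {s.majority}\n"
            )
            if s.exceptions:
                buf.write(f"# exceptions (minority sign): {', '.join(s.exceptions)}\n")
            else:
                buf.write("# exceptions: none\n")
        return buf.getvalue()


def _sign_of(ddi_sum: float) -> str:
    if abs(ddi_sum) < ZERO_TOL:
        return "zero"
    return "positive" if ddi_sum > 0 else "negative"


def delta_di(
    wt: DisorderProfile, mut: DisorderProfile, mutation: Mutation | None = None
) -> DeltaDIResult:
    """Element-wise mutant − wild-type profile difference, on the ×100 scale.

    Profiles must cover the same residue range and come from the same source
    kind (built-in scorer vs external predictor); mixing the two would make
    the difference meaningless.
    """
    if len(wt) != len(mut) or wt.start != mut.start:
        raise AlignmentError(
            f"profiles not aligned: wt {wt.start}+{len(wt)} vs mut {mut.start}+{len(mut)}"
        )
    if wt.source != mut.source:
        raise AlignmentError(f"profile sources differ: {wt.source} vs {mut.source}")
    delta = mut.as_array() - wt.as_array()
    ddi_sum = 100.0 * float(delta.sum())
    ddi_peak = 100.0 * float(np.abs(delta).max()) if delta.size else 0.0
    return DeltaDIResult(
        mutation=mutation,
        delta_profile=tuple(delta),
        ddi_sum=ddi_sum,
        ddi_peak=ddi_peak,
        sign=_sign_of(ddi_sum),
    )


def scan(
    window: SequenceWindow,
    catalog: MutationCatalog,
    scorer: ScorerParams | ScorerFn | None = None,
) -> ScanTable:
    """ΔDI for every catalog mutation against *window*, in catalog order.

    *scorer* is either :class:`ScorerParams` for the built-in scorer (the
    default) or any callable mapping a window to a profile.
    """
    report = validate_catalog(catalog, window)
    if not report.all_ok:
        bad = [e.mutation.name for e in report.entries if not e.ok]
        raise ValueError(f"catalog {catalog.name} does not validate against {window.id}: {bad}")

    if scorer is None or isinstance(scorer, ScorerParams):
        params = scorer or ScorerParams()
        scorer_fn: ScorerFn = lambda w: score_profile(w, params)
        scorer_name = "builtin"
    else:
        scorer_fn = scorer
        scorer_name = getattr(scorer, "__name__", "custom")

    wt_profile = scorer_fn(window)
    rows = []
    for m in catalog:
        mut_profile = scorer_fn(apply_mutation(window, m))
        rows.append(delta_di(wt_profile, mut_profile, mutation=m))
    return ScanTable(catalog.name, scorer_name, tuple(rows))


def scan_profiles(
    catalog: MutationCatalog,
    wt_profile: DisorderProfile,
    mutant_profiles: Mapping[str, DisorderProfile],
    scorer_name: str = "external",
) -> ScanTable:
    """Adapter-path scan from externally generated profiles.

    *mutant_profiles* maps mutation names (``'V717F'``) to parsed profiles —
    the route by which trained-predictor output (e.g. DISOPRED3) enters the
    pipeline.
    """
    rows = []
    for m in catalog:
        try:
            mut_profile = mutant_profiles[m.name]
        except KeyError:
            raise KeyError(f"no external profile supplied for mutation {m.name}") from None
        rows.append(delta_di(wt_profile, mut_profile, mutation=m))
    return ScanTable(catalog.name, scorer_name, tuple(rows))


def summarize_signs(table: ScanTable) -> SignSummary:
    """Majority sign, counts, and minority-sign ("exception") mutations."""
    if not table.rows:
        raise EmptyInputError("cannot summarize an empty scan table")
    signs = [r.sign for r in table.rows]
    n_pos, n_neg, n_zero = (signs.count(s) for s in ("positive", "negative", "zero"))
    counts = {"positive": n_pos, "negative": n_neg, "zero": n_zero}
    top = max(counts.values())
    leaders = [s for s, c in counts.items() if c == top]
    if len(leaders) > 1:
        majority = "no majority"
        exceptions: tuple[str, ...] = ()
    else:
        majority = leaders[0]
        exceptions = tuple(
            (r.mutation.name if r.mutation else "?")
            for r in table.rows
            if r.sign != majority
        )
    return SignSummary(n_pos, n_neg, n_zero, majority, exceptions)
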