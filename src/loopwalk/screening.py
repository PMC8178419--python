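"""Screening statistics for heat-treatment mutant libraries.

A screening record pairs a variant's enzymatic activity without heat
treatment with its residual activity after a heat challenge (here 60 degC
for 30 min, U/mL).  From these the module computes:

* thermostability activity — residual / untreated activity, as a percent;
* activity and residual activity relative to the wild-type enzyme;
* quadrant classification of mutants in the (relative activity,
  relative residual activity) plane, quadrant I being "more active and
  more thermostable than wild type";
* hit rates over a selected set of variants;
* synergy of a triple mutation versus its three single mutants, scored
  on a multiplicative (log-additive) null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "MutantRecord",
    "RelativeMeasures",
    "SynergyReport",
    "HitRate",
    "thermostability_activity",
    "reported_percent",
    "round_two_sig",
    "relative_to_wildtype",
    "quadrant_classify",
    "hit_rate",
    "synergy_score",
    "read_screen_table",
    "write_screen_table",
    "ScreenTableError",
]

SCREEN_COLUMNS = ["variant_id", "pos1", "pos2", "pos3", "activity_no_heat", "residual_activity"]
WILDTYPE_ID = "WT"


class ScreenTableError(ValueError):
    """Raised for malformed screening tables."""


@dataclass(frozen=True)
class MutantRecord:
    """One screened variant: residue identities plus paired activities (U/mL)."""

    variant_id: str
    triple: str  # three one-letter codes (or a single-substitution tag)
    activity_no_heat: float
    residual_activity: float

    def __post_init__(self) -> None:
        if not self.activity_no_heat > 0:
            raise ValueError(
                f"{self.variant_id}: activity without heat treatment must be > 0, "
                f"got {self.activity_no_heat}"
            )
        if self.residual_activity < 0:
            raise ValueError(
                f"{self.variant_id}: residual activity must be >= 0, "
                f"got {self.residual_activity}"
            )


def thermostability_activity(record: MutantRecord) -> float:
    """Percent activity retained after heat treatment (residual / untreated x 100)."""
    return 100.0 * record.residual_activity / record.activity_no_heat


def reported_percent(value: float) -> int:
    """Reporting convention for retained-activity percentages: nearest integer."""
    return int(math.floor(value + 0.5))


def round_two_sig(value: float) -> float:
    """Reporting convention for relative residual activity: two significant figures."""
    if value == 0:
        return 0.0
    return float(f"{value:.2g}")


@dataclass(frozen=True)
class RelativeMeasures:
    """A mutant's measures expressed against the wild-type enzyme (percent)."""

    percent_retained: float
    rel_activity_vs_wt: float
    rel_residual_vs_wt: float

    @property
    def reported_rel_residual(self) -> float:
        return round_two_sig(self.rel_residual_vs_wt)


def relative_to_wildtype(mutant: MutantRecord, wildtype: MutantRecord) -> RelativeMeasures:
    """Express a mutant's activities as percentages of the wild-type values."""
    if wildtype.residual_activity == 0:
        raise ValueError(
            "wild-type residual activity is zero; relative residual activity undefined"
        )
    return RelativeMeasures(
        percent_retained=thermostability_activity(mutant),
        rel_activity_vs_wt=100.0 * mutant.activity_no_heat / wildtype.activity_no_heat,
        rel_residual_vs_wt=100.0 * mutant.residual_activity / wildtype.residual_activity,
    )


def quadrant_classify(measures: RelativeMeasures) -> str:
    """Quadrant of the (relative activity, relative residual) plane at (100, 100).

    I: both improved; II: more stable only; III: neither; IV: more active
    only.  Values exactly at 100% count as non-improved.
    """
    improved_activity = measures.rel_activity_vs_wt > 100.0
    improved_residual = measures.rel_residual_vs_wt > 100.0
    if improved_activity and improved_residual:
        return "I"
    if improved_residual:
        return "II"
    if improved_activity:
        return "IV"
    return "III"


# named hit criteria usable by ``hit_rate``
HIT_CRITERIA: dict[str, Callable[[object], bool]] = {
    "first_quadrant": lambda m: quadrant_classify(m) == "I",
    "improved_residual": lambda m: m.rel_residual_vs_wt > 100.0,
}


@dataclass(frozen=True)
class HitRate:
    successes: int
    total: int

    @property
    def fraction(self) -> float:
        return self.successes / self.total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def hit_rate(
    selected: Sequence, criterion: str | Callable[[object], bool] | None = None
) -> HitRate:
    """Fraction of selected variants meeting a success criterion.

    ``criterion`` may be a callable, the name of a registered predicate
    (``"first_quadrant"``, ``"improved_residual"``), or ``None`` when
    ``selected`` is already a sequence of booleans.
    """
    if len(selected) == 0:
        raise ValueError("hit rate of an empty selection is undefined")
    if criterion is None:
        outcomes = [bool(x) for x in selected]
    else:
        pred = HIT_CRITERIA[criterion] if isinstance(criterion, str) else criterion
        outcomes = [bool(pred(x)) for x in selected]
    return HitRate(successes=sum(outcomes), total=len(outcomes))


@dataclass(frozen=True)
class SynergyReport:
    """Triple-mutant synergy on a multiplicative null (log10 units).

    ``synergy`` is the observed log10 relative-residual fraction of the
    triple minus the sum of the single-mutant log10 fractions; zero means
    the triple effect equals the product of the single effects, positive
    means super-multiplicative.
    """

    observed_log_rel_residual: float
    expected_log_rel_residual: float

    @property
    def synergy(self) -> float:
        return self.observed_log_rel_residual - self.expected_log_rel_residual


def synergy_score(
    triple_rel_residual_pct: float, single_rel_residual_pcts: Iterable[float]
) -> SynergyReport:
    """Score a triple mutant against its three single mutants.

    Inputs are relative residual activities versus wild type, in percent
    (100 = wild-type-like).  Symmetric under permutation of the singles.
    """
    singles = list(single_rel_residual_pcts)
    if triple_rel_residual_pct <= 0 or any(s <= 0 for s in singles):
        raise ValueError("relative residual activities must be > 0 to take logs")
    observed = math.log10(triple_rel_residual_pct / 100.0)
    expected = sum(math.log10(s / 100.0) for s in singles)
    return SynergyReport(
        observed_log_rel_residual=observed, expected_log_rel_residual=expected
    )


# ---------------------------------------------------------------------- #
# screening-table I/O (TSV dialect shared with the synthetic generator)


def read_screen_table(path: str | Path) -> tuple[list[MutantRecord], MutantRecord]:
    """Read a screening TSV into mutant records plus the wild-type record.

    Expected columns: ``variant_id, pos1, pos2, pos3, activity_no_heat,
    residual_activity``; exactly one row must carry the reserved
    ``variant_id`` ``WT``.  Malformed rows are reported with their line
    number (1-based, counting the header as line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ScreenTableError(f"{path}: empty screening table") from None
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenTableError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ScreenTableError(f"{path}: screening table has no data rows")

    records: list[MutantRecord] = []
    wildtype: MutantRecord | None = None
    for i, row in df.iterrows():
        line = i + 2
        try:
            rec = MutantRecord(
                variant_id=str(row["variant_id"]),
                triple=str(row["pos1"]) + str(row["pos2"]) + str(row["pos3"]),
                activity_no_heat=float(row["activity_no_heat"]),
                residual_activity=float(row["residual_activity"]),
            )
        except (ValueError, TypeError) as exc:
            raise ScreenTableError(f"{path}:{line}: {exc}") from None
        if rec.variant_id == WILDTYPE_ID:
            if wildtype is not None:
                raise ScreenTableError(f"{path}:{line}: duplicate {WILDTYPE_ID} row")
            wildtype = rec
        else:
            records.append(rec)
    if wildtype is None:
        raise ScreenTableError(f"{path}: no wild-type row (variant_id == '{WILDTYPE_ID}')")
    return records, wildtype


def write_screen_table(
    records: Iterable[MutantRecord], wildtype: MutantRecord, path: str | Path
) -> None:
    """Write records (wild type first) in the screening TSV dialect."""
    rows = [wildtype, *records]
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in rows],
            "pos1": [r.triple[0] for r in rows],
            "pos2": [r.triple[1] for r in rows],
            "pos3": [r.triple[2] for r in rows],
            "activity_no_heat": [r.activity_no_heat for r in rows],
            "residual_activity": [r.residual_activity for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
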