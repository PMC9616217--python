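"""Cohort-level statistics: group comparisons, correlations, diameter agreement.

Thin, audited plumbing around scipy.stats/statsmodels.  The unpaired t test
defaults to the Welch (unequal-variance) form; the pooled-variance Student
form is available behind ``welch=False`` and the choice is recorded in the
result.  Raw p-values are reported by default; Holm adjustment across a
family of tests is available via :func:`adjust_pvalues`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .io import records_to_frame
from .model import CaseRecord

TableLike = Union[Sequence[CaseRecord], pd.DataFrame]


@dataclass
class ComparisonResult:
    test_name: str  # unpaired_t | fisher_exact | pearson
    statistic: float
    p_value: float
    n: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class AgreementResult:
    """Pearson r plus mean signed error (measured − manual, mm)."""

    r: float
    mean_error_mm: float
    n: int
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r| must be <= 1, got {self.r}")


def _as_frame(table: TableLike) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return records_to_frame(table)


def _column(frame: pd.DataFrame, name: str) -> pd.Series:
    if name not in frame.columns:
        raise ValidationError(f"no column {name!r} in cohort table; have {list(frame.columns)}")
    return pd.to_numeric(frame[name], errors="coerce")


def compare_groups(
    table: TableLike, metric: str, by: str = "group", welch: bool = True
) -> ComparisonResult:
    """Unpaired two-sided t test of ``metric`` between the two groups.

    Requires at least two defined values per group.  Group levels are taken
    in sorted order, so the reported mean difference is first-level minus
    second-level (e.g. control minus pancreatic_cancer).  If every value in
    both groups is identical the comparison is vacuous and p = 1.0 is
    returned by convention (recorded in the result detail).
    """
    frame = _as_frame(table)
    values = _column(frame, metric)
    if by not in frame.columns:
        raise ValidationError(f"no grouping column {by!r}")
    groups = frame[by].astype(str)
    levels = sorted(g for g in groups.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"grouping column {by!r} must have exactly 2 levels, got {levels}")
    a = values[groups == levels[0]].dropna().to_numpy(float)
    b = values[groups == levels[1]].dropna().to_numpy(float)
    for name, arr in ((levels[0], a), (levels[1], b)):
        if len(arr) < 2:
            raise InsufficientDataError(
                f"group {name!r} has {len(arr)} defined values for {metric!r}; need >= 2"
            )
    n = {levels[0]: len(a), levels[1]: len(b)}
    diff = float(np.mean(a) - np.mean(b))
    effect = {
        f"mean_{levels[0]}": float(np.mean(a)),
        f"mean_{levels[1]}": float(np.mean(b)),
        "mean_difference": diff,
    }
    if np.ptp(a) == 0 and np.ptp(b) == 0 and np.mean(a) == np.mean(b):
        return ComparisonResult(
            "unpaired_t", 0.0, 1.0, n, effect,
            {"welch": welch, "convention": "identical constant values in both groups: p = 1.0"},
        )
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult("unpaired_t", float(t), float(p), n, effect, {"welch": welch})


def fisher_exact(table_2x2: Sequence[Sequence[int]]) -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    arr = np.asarray(table_2x2, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValidationError("Fisher's exact needs a non-negative 2x2 table")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return ComparisonResult(
        "fisher_exact",
        float(odds),
        float(p),
        n={"total": int(arr.sum())},
        effect={"odds_ratio": float(odds)},
    )


def correlate(table: TableLike, x: str, y: str) -> ComparisonResult:
    """Pearson correlation with two-sided p; scatter pairs are included in
    the result detail for plotting."""
    frame = _as_frame(table)
    xs = _column(frame, x)
    ys = _column(frame, y)
    ok = xs.notna() & ys.notna()
    xv = xs[ok].to_numpy(float)
    yv = ys[ok].to_numpy(float)
    if len(xv) < 3:
        raise InsufficientDataError(f"need >= 3 paired values of {x!r}/{y!r}, got {len(xv)}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError(f"zero variance in {x!r} or {y!r}; correlation undefined")
    res = sps.pearsonr(xv, yv)
    return ComparisonResult(
        "pearson",
        float(res.statistic),
        float(res.pvalue),
        n={"pairs": len(xv)},
        effect={"r": float(res.statistic)},
        detail={"pairs": np.stack([xv, yv], axis=1)},
    )


def diameter_agreement(
    table: TableLike,
    manual: str = "manual_duct_diameter_mm",
    measured: str = "measured_duct_diameter_mm",
) -> AgreementResult:
    """Agreement between manual and mask-derived duct diameters: Pearson r
    and mean signed error (measured − manual, in mm)."""
    frame = _as_frame(table)
    m = _column(frame, manual)
    a = _column(frame, measured)
    ok = m.notna() & a.notna()
    mv = m[ok].to_numpy(float)
    av = a[ok].to_numpy(float)
    if len(mv) < 3:
        raise InsufficientDataError(f"need >= 3 cases with both diameters, got {len(mv)}")
    err = float(np.mean(av - mv))
    if np.ptp(mv) == 0 or np.ptp(av) == 0:
        # exact agreement up to a constant offset: correlation degenerate
        raise DegenerateDataError("zero variance in diameters; agreement r undefined")
    res = sps.pearsonr(mv, av)
    return AgreementResult(r=float(res.statistic), mean_error_mm=err, n=len(mv), p_value=float(res.pvalue))


def adjust_pvalues(p_values: Sequence[float], method: str = "holm") -> np.ndarray:
    """Multiplicity adjustment across a family of comparisons (opt-in)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]
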