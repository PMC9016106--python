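"""Cohort-level summaries and group comparisons.

Produces the machine-readable analogue of a clinical baseline table and a
volume-comparison table: per-variable mean ± sd by group with the test
appropriate to each variable —

* continuous baseline/metabolic variables (age, SUVmax, T/N ratio,
  Nmax/Nmean, per-ROI SUVmean and volume): Welch two-sample t-test;
* sex distribution: Fisher's exact test on the 2×2 table;
* concordance scores (DICE, overlap volume) and margin statistics:
  Wilcoxon rank-sum test (exact for small samples without ties);
* within-group MRI-ROI vs PET-ROI SUVmean: Wilcoxon signed-rank test
  (zero differences dropped, exact conditional distribution for small n).

No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import LesionMetrics
from .segmentation import ReferenceStats

__all__ = [
    "PatientRecord",
    "TestResult",
    "CohortResult",
    "summarize",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "t_test_independent",
    "fisher_exact",
    "build_cohort_tables",
    "GROUP_DIFFUSE",
    "GROUP_CIRCUMSCRIBED",
]

GROUP_DIFFUSE = "diffuse"
GROUP_CIRCUMSCRIBED = "circumscribed"

_EXACT_RANKSUM_MAX_N = 25
_EXACT_SIGNEDRANK_MAX_N = 50


@dataclass(frozen=True)
class PatientRecord:
    """One patient: group label, demographics and per-lesion metrics."""

    id: str
    group: str
    age: float
    sex: str
    metrics: LesionMetrics
    ref: ReferenceStats | None = None

    def __post_init__(self):
        if self.group not in (GROUP_DIFFUSE, GROUP_CIRCUMSCRIBED):
            raise ValueError(f"unknown group label {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex label {self.sex!r}")


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample sd (n−1 denominator)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least two values for a sample sd")
    return float(arr.mean()), float(arr.std(ddof=1))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution when n_x + n_y ≤ 25 and the pooled sample has
    no ties; otherwise the normal approximation with tie and continuity
    correction.  The statistic reported is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    rank_sum_x = float(res.statistic + x.size * (x.size + 1) / 2.0)
    return TestResult("wilcoxon_rank_sum", rank_sum_x, float(res.pvalue))


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact conditional two-sided p for the signed-rank statistic.

    Convolves the distribution of W+ over all 2^n equiprobable sign
    assignments of the observed (mid)ranks.  Midranks are multiples of
    0.5, so 2·W+ is integer-valued and the distribution fits in an
    integer-indexed array.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    assert abs(dist.sum() - 1.0) < 1e-9
    w2 = int(round(2 * w_plus))
    p_low = dist[: w2 + 1].sum()
    p_high = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment).  For
    n ≤ 50 nonzero differences the p-value is exact, computed by
    convolution over sign assignments of the observed midranks (valid
    with ties); beyond that, the tie-corrected normal approximation.
    The statistic is W+, the rank sum of positive differences.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= _EXACT_SIGNEDRANK_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="approx")
        p = float(res.pvalue)
    return TestResult("wilcoxon_signed_rank", w_plus, p)


def t_test_independent(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult("welch_t", 0.0, 1.0)
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue))


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p))


# variable -> (record accessor column, test family)
_TTEST_VARS = [
    "age",
    "suv_max",
    "tn_ratio",
    "n_max",
    "n_mean",
    "suv_mean_mri",
    "suv_mean_fby",
    "volume_mri_ml",
    "volume_fby_ml",
]
_RANKSUM_VARS = ["dice", "overlap_volume", "suv_mean_margin", "margin_over_nmax"]


@dataclass
class CohortResult:
    """Group-comparison summary: one row per variable plus paired tests."""

    n_diffuse: int
    n_circumscribed: int
    variables: pd.DataFrame
    sex_table: np.ndarray
    paired: dict[str, TestResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_diffuse": self.n_diffuse,
            "n_circumscribed": self.n_circumscribed,
            "sex_table": self.sex_table.tolist(),
            "variables": self.variables.reset_index().to_dict(orient="records"),
            "paired": {
                k: {"test": v.test, "statistic": v.statistic, "p": v.p_value}
                for k, v in self.paired.items()
            },
        }


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into one metrics row per patient."""
    rows = []
    for r in records:
        m = r.metrics
        rows.append(
            {
                "id": r.id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "volume_mri_ml": m.volume_mri_ml,
                "volume_fby_ml": m.volume_fby_ml,
                "overlap_volume": m.overlap_volume,
                "dice": m.dice,
                "suv_max": m.suv_max,
                "tn_ratio": m.tn_ratio,
                "suv_mean_mri": m.suv_mean_mri,
                "suv_mean_fby": m.suv_mean_fby,
                "suv_mean_margin": m.suv_mean_margin,
                "margin_over_nmax": m.margin_over_nmax,
                "margin_volume_ml": m.margin_volume_ml,
                "n_max": m.n_max,
                "n_mean": m.n_mean,
            }
        )
    return pd.DataFrame(rows)


def build_cohort_tables(records: Sequence[PatientRecord]) -> CohortResult:
    """Compare the diffuse and circumscribed groups variable by variable.

    Margin variables are undefined (NaN) for patients whose MRI ROI
    covers the whole PET ROI; those patients are excluded from the
    margin comparisons only.
    """
    frame = records_to_frame(records)
    return build_cohort_tables_from_frame(frame)


def build_cohort_tables_from_frame(frame: pd.DataFrame) -> CohortResult:
    """Same as :func:`build_cohort_tables`, from a per-patient metrics frame."""
    groups = frame.groupby("group")
    if GROUP_DIFFUSE not in groups.groups or GROUP_CIRCUMSCRIBED not in groups.groups:
        raise ValueError("both groups must be represented in the cohort")
    diff = frame[frame["group"] == GROUP_DIFFUSE]
    circ = frame[frame["group"] == GROUP_CIRCUMSCRIBED]

    rows = {}
    for var in _TTEST_VARS + _RANKSUM_VARS:
        if var not in frame.columns:
            continue
        xd = diff[var].dropna().to_numpy()
        xc = circ[var].dropna().to_numpy()
        if len(xd) >= 2 and len(xc) >= 2:
            if var in _TTEST_VARS:
                result = t_test_independent(xd, xc)
            else:
                result = wilcoxon_rank_sum(xd, xc)
            md, sd = summarize(xd)
            mc, sc = summarize(xc)
        else:
            # a margin variable can be undefined for most of a group
            # (empty margins); report what is defined, no test
            nan = float("nan")
            result = TestResult("undefined", nan, nan)
            md = float(np.mean(xd)) if len(xd) else nan
            sd = float(np.std(xd, ddof=1)) if len(xd) >= 2 else nan
            mc = float(np.mean(xc)) if len(xc) else nan
            sc = float(np.std(xc, ddof=1)) if len(xc) >= 2 else nan
        rows[var] = {
            "diffuse_mean": md,
            "diffuse_sd": sd,
            "circumscribed_mean": mc,
            "circumscribed_sd": sc,
            "n_diffuse": len(xd),
            "n_circumscribed": len(xc),
            "test": result.test,
            "statistic": result.statistic,
            "p": result.p_value,
        }
    variables = pd.DataFrame.from_dict(rows, orient="index")
    variables.index.name = "variable"

    sex_table = np.array(
        [
            [(diff["sex"] == "male").sum(), (circ["sex"] == "male").sum()],
            [(diff["sex"] == "female").sum(), (circ["sex"] == "female").sum()],
        ],
        dtype=int,
    )
    sex_result = fisher_exact(sex_table)
    variables.loc["sex"] = {
        "diffuse_mean": float(sex_table[0, 0]),
        "diffuse_sd": float(sex_table[1, 0]),
        "circumscribed_mean": float(sex_table[0, 1]),
        "circumscribed_sd": float(sex_table[1, 1]),
        "n_diffuse": len(diff),
        "n_circumscribed": len(circ),
        "test": sex_result.test,
        "statistic": sex_result.statistic,
        "p": sex_result.p_value,
    }

    paired = {}
    for label, sub in (("diffuse", diff), ("circumscribed", circ), ("all", frame)):
        try:
            result = wilcoxon_signed_rank(
                sub["suv_mean_mri"].to_numpy(), sub["suv_mean_fby"].to_numpy()
            )
        except ValueError:
            if label == "all":
                # the whole cohort has MRI ROI == PET ROI: surface it
                raise
            result = TestResult("undefined", float("nan"), float("nan"))
        paired[f"suv_mean_mri_vs_fby_{label}"] = result

    return CohortResult(
        n_diffuse=len(diff),
        n_circumscribed=len(circ),
        variables=variables,
        sex_table=sex_table,
        paired=paired,
    )
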