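"""Validation statistics for the two stress classifiers.

Agreement with manual inspection is summarized per timepoint as the
percentage of matching binary calls; its support is a Pearson chi-squared
goodness-of-fit test of the (match, mismatch) counts against an equal
split.  Projected leaf areas are compared between treatments with a
two-tailed heteroscedastic (Welch) t-test, and survival differences
between lines with a Cochran-Mantel-Haenszel test over stratified 2x2
tables.  No multiple-testing correction is applied: per-DAS tests are
reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging_io import round_half_away

__all__ = [
    "AgreementRecord",
    "GofResult",
    "WelchResult",
    "CMHResult",
    "percent_reduction",
    "agreement",
    "gof_chi2",
    "welch_t_test",
    "cmh_test",
    "area_series",
    "survival_summary",
]


def percent_reduction(reference: float, value: float) -> float:
    """Percent by which ``value`` falls short of ``reference``.

    E.g. fill capacities of two container types: 100 * (ref - val) / ref.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - value) / reference


@dataclass(frozen=True)
class AgreementRecord:
    """Classifier-vs-inspection match counts at one timepoint."""

    das: int
    classifier: str
    matches: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.total or self.total <= 0:
            raise ValueError("need 0 <= matches <= total, total > 0")

    @property
    def percent(self) -> int:
        """Agreement percentage, rounded half away from zero."""
        return int(round_half_away(100.0 * self.matches / self.total))


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    pvalue: float


@dataclass(frozen=True)
class CMHResult:
    statistic: float
    pvalue: float


def agreement(
    predicted: Mapping[str, str],
    inspected: Mapping[str, str],
    das: int,
    classifier: str = "classifier",
) -> AgreementRecord:
    """Count matching binary health calls over a common sample set."""
    if set(predicted) != set(inspected) or not predicted:
        raise ValueError("classifier and inspection labels must cover the same non-empty sample set")
    matches = sum(1 for k in predicted if predicted[k] == inspected[k])
    return AgreementRecord(das=das, classifier=classifier, matches=matches, total=len(predicted))


def gof_chi2(matches: int, total: int) -> GofResult:
    """Pearson goodness-of-fit of (match, mismatch) against an equal split.

    Observed (m, n - m) vs expected (n/2, n/2), one degree of freedom, no
    continuity correction; p is the upper chi-squared tail (equivalently
    erfc(sqrt(chi2 / 2)) at df = 1).
    """
    if total < 1:
        raise ValueError("total must be at least 1")
    if not 0 <= matches <= total:
        raise ValueError("matches must lie in [0, total]")
    stat = (2.0 * matches - total) ** 2 / total
    return GofResult(statistic=stat, df=1, pvalue=float(sps.chi2.sf(stat, df=1)))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-tailed unequal-variance t-test with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return WelchResult(statistic=0.0, df=float(x.size + y.size - 2), pvalue=1.0)
        raise ValueError("both variances are zero with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    se2 = vx / x.size + vy / y.size
    df = se2**2 / ((vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1))
    return WelchResult(statistic=float(res.statistic), df=float(df), pvalue=float(res.pvalue))


def cmh_test(tables: np.ndarray | Sequence[np.ndarray], correction: bool = True) -> CMHResult:
    """Cochran-Mantel-Haenszel test over K stratified 2x2 tables.

    ``tables`` is (K, 2, 2) (or a list of 2x2 arrays) of non-negative
    counts; every stratum must have a positive total.  The continuity
    correction is on by default, matching the common statistical-
    environment default; df = 1, upper-tail p.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    arr = np.asarray(tables, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[1:] != (2, 2):
        raise ValueError("tables must be (K, 2, 2)")
    if arr.min() < 0:
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=(1, 2)) <= 0):
        raise ValueError("every stratum must have a positive total")
    # statsmodels expects (2, 2, K)
    st = StratifiedTable(np.moveaxis(arr, 0, 2))
    res = st.test_null_odds(correction=correction)
    return CMHResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def area_series(plants: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- standard error of projected leaf area per group.

    Input columns: sample_id, line, treatment, das, area (missing plants
    omitted or area = NaN).  Output: line, treatment, das, mean, se, n;
    the SE of a single observation is reported as missing.
    """
    df = plants.dropna(subset=["area"])
    grouped = (
        df.groupby(["line", "treatment", "das"])["area"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    grouped["se"] = grouped["sd"] / np.sqrt(grouped["n"])
    grouped.loc[grouped["n"] < 2, "se"] = np.nan
    return grouped[["line", "treatment", "das", "mean", "se", "n"]]


def survival_summary(final_labels: pd.DataFrame) -> pd.DataFrame:
    """Alive/dead percentages per line over the water-limited group.

    Input columns: sample_id, line, treatment, final_status (alive/dead).
    """
    df = final_labels[final_labels["treatment"] == "water-limited"]
    bad = set(df["final_status"]) - {"alive", "dead"}
    if bad:
        raise ValueError(f"unknown final statuses present: {sorted(bad)}")
    rows = []
    for line, grp in df.groupby("line"):
        n = len(grp)
        alive = int((grp["final_status"] == "alive").sum())
        rows.append(
            {
                "line": line,
                "n": n,
                "pct_alive": 100.0 * alive / n,
                "pct_dead": 100.0 * (n - alive) / n,
            }
        )
    return pd.DataFrame(rows, columns=["line", "n", "pct_alive", "pct_dead"])
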