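"""Per-feature hypothesis testing and detected-feature counting.

One-way ANOVA across extraction groups, Welch's two-sample t tests against a
reference extraction, Bonferroni adjustment, and the star-category binning
used throughout the result figures.  Tests run on (batch-corrected) peak
areas; missing values are dropped per group, never imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .feature_io import STUDY_GROUPS, FeatureTable

__all__ = [
    "TestResult",
    "FeatureCountResult",
    "DetectionRule",
    "anova_oneway",
    "welch_t",
    "bonferroni",
    "significance_category",
    "count_detected_features",
    "anova_matrix",
    "welch_matrix",
]

#: Contrasts evaluated on feature counts: each non-reference extraction vs the
#: reference, plus bead-homogenized variants vs their base method.
DEFAULT_COUNT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("II", "I"), ("III", "I"), ("IV", "I"), ("III_B", "III"), ("IV_B", "IV"),
)


@dataclass
class TestResult:
    """Outcome of a single univariate test."""

    unit_id: str
    contrast: str
    statistic: float
    df: tuple[float, ...]
    p_raw: float
    p_adj: float
    category: str
    degenerate: bool = False

    def adjusted(self, p_adj: float) -> "TestResult":
        return TestResult(self.unit_id, self.contrast, self.statistic, self.df,
                          self.p_raw, p_adj, significance_category(p_adj),
                          self.degenerate)


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def anova_oneway(groups: Sequence[Sequence[float]], unit_id: str = "",
                 contrast: str = "anova") -> TestResult:
    """Classical fixed-effects one-way ANOVA.

    Missing values are dropped per group.  When both the between- and
    within-group sums of squares are zero the result is flagged degenerate
    with p = 1.
    """
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2:
        raise ValueError("anova_oneway requires at least 2 groups")
    for i, g in enumerate(cleaned):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 non-missing values")
    k = len(cleaned)
    n_total = sum(len(g) for g in cleaned)
    grand = np.concatenate(cleaned).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in cleaned)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in cleaned)
    df_b, df_w = float(k - 1), float(n_total - k)
    if ssw == 0.0 and ssb == 0.0:
        return TestResult(unit_id, contrast, 0.0, (df_b, df_w), 1.0, 1.0, "ns",
                          degenerate=True)
    if ssw == 0.0:
        return TestResult(unit_id, contrast, np.inf, (df_b, df_w), 0.0, 0.0, "****")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(unit_id, contrast, float(f), (df_b, df_w), p, p,
                      significance_category(p))


def welch_t(a: Sequence[float], b: Sequence[float], unit_id: str = "",
            contrast: str = "welch") -> TestResult:
    """Welch's unequal-variance two-sample t test, two-sided.

    Two constant and equal samples yield t = 0, p = 1 (flagged degenerate).
    """
    x, y = _clean(a), _clean(b)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires >= 2 non-missing values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(unit_id, contrast, 0.0, (float(len(x) + len(y) - 2),),
                              1.0, 1.0, "ns", degenerate=True)
        return TestResult(unit_id, contrast, np.inf if x.mean() > y.mean() else -np.inf,
                          (float(len(x) + len(y) - 2),), 0.0, 0.0, "****")
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(unit_id, contrast, float(t), (float(df),), p, p,
                      significance_category(p))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p); order-preserving."""
    p = np.asarray(p_values, dtype=float)
    finite = p[~np.isnan(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} is smaller than the number of p values ({p.size})")
    return np.minimum(1.0, m * p)


def significance_category(p: float) -> str:
    """Map a p value onto the star categories (ns / * / ** / *** / ****)."""
    if np.isnan(p):
        return "ns"
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value out of range: {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# -- vectorized engines (used by simulations and feature selection) ---------


def anova_matrix(data: np.ndarray, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nan-aware one-way ANOVA over the columns of ``data``.

    Parameters
    ----------
    data
        Array of shape (n_samples, n_units); NaN entries are dropped per group.
    labels
        Group label per row.

    Returns
    -------
    (F, p) arrays of length n_units.  Units where any group has fewer than 2
    usable values, or with zero variance everywhere, get NaN / 1.0 as
    appropriate (zero-variance-everywhere units get p = 1).
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("anova_matrix requires at least 2 groups")
    valid = ~np.isnan(data)
    counts, means = [], []
    ssw = np.zeros(data.shape[1])
    usable = np.ones(data.shape[1], dtype=bool)
    for g in groups:
        rows = labels == g
        sub = data[rows]
        n_g = valid[rows].sum(axis=0)
        usable &= n_g >= 2
        with np.errstate(invalid="ignore"):
            m_g = np.nansum(sub, axis=0) / np.where(n_g > 0, n_g, 1)
            ssw += np.nansum((sub - m_g) ** 2, axis=0)
        counts.append(n_g)
        means.append(m_g)
    counts_arr = np.array(counts, dtype=float)
    means_arr = np.array(means)
    n_tot = counts_arr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (counts_arr * means_arr).sum(axis=0) / n_tot
        ssb = (counts_arr * (means_arr - grand) ** 2).sum(axis=0)
    k = len(groups)
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = np.full(data.shape[1], np.nan)
    ok = usable & (ssw > 0)
    p[ok] = sps.f.sf(f[ok], df_b, df_w[ok])
    degenerate = usable & (ssw == 0) & (ssb == 0)
    p[degenerate] = 1.0
    f[degenerate] = 0.0
    exploded = usable & (ssw == 0) & (ssb > 0)
    p[exploded] = 0.0
    f[~usable] = np.nan
    p[~usable] = np.nan
    return f, p


def welch_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nan-aware Welch t test over columns of ``a`` vs ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = (~np.isnan(a)).sum(axis=0)
    nb = (~np.isnan(b)).sum(axis=0)
    usable = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        va = np.nansum((a - ma) ** 2, axis=0) / np.maximum(na - 1, 1)
        vb = np.nansum((b - mb) ** 2, axis=0) / np.maximum(nb - 1, 1)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / np.maximum(na - 1, 1)
                         + (vb / nb) ** 2 / np.maximum(nb - 1, 1))
    p = np.full(a.shape[1], np.nan)
    ok = usable & (se2 > 0)
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])
    tied = usable & (se2 == 0)
    p[tied] = np.where(ma[tied] == mb[tied], 1.0, 0.0)
    t[tied] = np.where(ma[tied] == mb[tied], 0.0, np.inf)
    t[~usable] = np.nan
    return t, p


# -- detected-feature counting ----------------------------------------------


@dataclass(frozen=True)
class DetectionRule:
    """Per-sample detection predicate: non-missing and area > min_area."""

    min_area: float = 0.0

    def detected(self, areas: np.ndarray) -> np.ndarray:
        return ~np.isnan(areas) & (areas > self.min_area)


@dataclass
class FeatureCountResult:
    """Per-sample detected-feature counts with group summaries and contrasts."""

    per_sample: pd.Series            # sample_id -> count (study samples only)
    group_mean: pd.Series            # group -> mean count
    group_sd: pd.Series              # group -> sample SD of counts
    anova: TestResult | None
    contrasts: list[TestResult] = field(default_factory=list)


def count_detected_features(table: FeatureTable,
                            rule: DetectionRule = DetectionRule(),
                            contrasts: Sequence[tuple[str, str]] = DEFAULT_COUNT_CONTRASTS,
                            ) -> FeatureCountResult:
    """Count detected features per study sample and test group contrasts.

    Counts are per-sample (the within-group spread across replicates is part
    of the result).  A one-way ANOVA over all study groups present plus
    Welch contrasts from ``contrasts`` (skipping absent groups) are attached.
    """
    study = table.study_sample_ids
    detected = rule.detected(table.areas[study].to_numpy(dtype=float))
    counts = pd.Series(detected.sum(axis=0), index=study, name="detected_features")
    groups = table.samples.loc[study, "group"]
    group_mean = counts.groupby(groups).mean()
    group_sd = counts.groupby(groups).std(ddof=1)
    order = [g for g in STUDY_GROUPS if g in group_mean.index]
    group_mean = group_mean.loc[order]
    group_sd = group_sd.loc[order]

    anova_res = None
    by_group = {g: counts[groups == g].to_numpy(dtype=float) for g in order}
    testable = [g for g in order if len(by_group[g]) >= 2]
    if len(testable) >= 2:
        anova_res = anova_oneway([by_group[g] for g in testable],
                                 unit_id="feature_count",
                                 contrast="ANOVA:" + "|".join(testable))
    results = []
    for g, ref in contrasts:
        if g in by_group and ref in by_group and len(by_group[g]) >= 2 and len(by_group[ref]) >= 2:
            results.append(welch_t(by_group[g], by_group[ref], unit_id="feature_count",
                                   contrast=f"{g} vs {ref}"))
    return FeatureCountResult(counts, group_mean, group_sd, anova_res, results)
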