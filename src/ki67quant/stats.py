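"""Cohort aggregation and nonparametric group statistics.

Per-slide summaries are grouped by tumor family/type into descriptive
tables (median, mean, sd, min, max of labeling index and cell densities).
Group differences use the tie-corrected Kruskal–Wallis rank test with
Bonferroni adjustment; agreement between two scoring methods is measured
with Spearman's ρ, the two-way random-effects absolute-agreement single-
measurement intraclass correlation ICC(2,1), and an ordinary least-squares
regression line.  The rank and ANOVA decompositions are computed from first
principles here; library implementations serve as cross-checks in the test
suite, not as the computation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

METRICS = ("li_percent", "pos_density", "neg_density")


@dataclasses.dataclass
class SlideSummary:
    """Per-slide record feeding the cohort table."""

    slide_id: str
    group: str = ""
    descriptor: str | None = None
    n_pos: int = 0
    n_neg: int = 0
    area_mm2: float = 0.0
    dab_threshold: float | None = None
    weak_hematoxylin: bool = False

    @property
    def li_percent(self) -> float:
        total = self.n_pos + self.n_neg
        return math.nan if total == 0 else 100.0 * self.n_pos / total

    @property
    def pos_density(self) -> float:
        return self.n_pos / self.area_mm2 if self.area_mm2 > 0 else math.nan

    @property
    def neg_density(self) -> float:
        return self.n_neg / self.area_mm2 if self.area_mm2 > 0 else math.nan


def summaries_frame(summaries: list[SlideSummary]) -> pd.DataFrame:
    rows = [
        {
            "slide_id": s.slide_id,
            "group": s.group,
            "descriptor": s.descriptor,
            "n_pos": s.n_pos,
            "n_neg": s.n_neg,
            "area_mm2": s.area_mm2,
            "li_percent": s.li_percent,
            "pos_density": s.pos_density,
            "neg_density": s.neg_density,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def summarize_by_group(summaries: list[SlideSummary]) -> pd.DataFrame:
    """Descriptive statistics per group, ordered by descending median LI.

    NA metric values (slides with zero detections) are excluded per metric;
    the standard deviation of a single-slide group is reported as NA rather
    than zero, since one observation carries no spread information.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")
    df = summaries_frame(summaries)
    records = []
    for group, sub in df.groupby("group", sort=False):
        rec: dict[str, object] = {"group": group, "n_slides": len(sub)}
        for metric in METRICS:
            vals = sub[metric].dropna()
            rec[f"{metric}_median"] = vals.median() if len(vals) else math.nan
            rec[f"{metric}_mean"] = vals.mean() if len(vals) else math.nan
            rec[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
            rec[f"{metric}_min"] = vals.min() if len(vals) else math.nan
            rec[f"{metric}_max"] = vals.max() if len(vals) else math.nan
        records.append(rec)
    table = pd.DataFrame(records)
    # group name as tie-break keeps the table order deterministic
    return table.sort_values(
        ["li_percent_median", "group"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    H = (12 / (N(N+1))) Σ R_i²/n_i − 3(N+1), divided by the tie correction
    1 − Σ(t³−t)/(N³−N); the p-value comes from chi-square with k−1 degrees
    of freedom.  All-identical observations give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)   # average ranks for ties
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[start:start + len(g)].sum() ** 2 / len(g)
        for g, start in zip(groups, np.cumsum([0] + [len(g) for g in groups[:-1]]))
    ) - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction <= 0:        # all observations identical
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def bonferroni_adjust(
    p_values: list[float], alpha: float = 0.05
) -> tuple[list[float], list[bool]]:
    """Bonferroni family-wise correction: p_adj = min(1, m·p)."""
    p_values = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p_values)
    adjusted = [min(1.0, m * p) for p in p_values]
    flags = [p < alpha for p in adjusted]
    return adjusted, flags


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def icc_2_1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n×2 ratings table
    (targets × raters):

        ICC = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)

    Negative estimates are reported as computed, not clamped.
    """
    data = np.stack([x, y], axis=1).astype(float)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        return math.nan
    return float((msr - mse) / denom)


def agreement_stats(x, y) -> dict[str, float]:
    """Method-agreement summary between two paired score vectors.

    Returns Spearman's ρ (average ranks for ties), ICC(2,1), and the OLS
    slope/intercept of y on x.  With zero variance in either vector the
    correlation measures are NA.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NA values are not allowed in agreement vectors")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho = icc = math.nan
    else:
        rho = _spearman(x, y)
        icc = icc_2_1(x, y)
    if np.ptp(x) == 0:
        slope, intercept = math.nan, math.nan
    else:
        slope, intercept = np.polyfit(x, y, 1)
    return {
        "spearman_rho": rho,
        "icc": icc,
        "slope": float(slope),
        "intercept": float(intercept),
    }


def boxplot_table(summaries: list[SlideSummary], metric: str = "li_percent") -> pd.DataFrame:
    """Quartile/whisker table underlying the per-group box plot.

    Whiskers follow the Tukey convention: most extreme observation within
    1.5 IQR of the box.  Emitting the numbers alongside the figure makes the
    plot testable without pixel comparison.
    """
    df = summaries_frame(summaries)
    rows = []
    for group, sub in df.groupby("group", sort=False):
        vals = sub[metric].dropna().to_numpy()
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                "group": group,
                "metric": metric,
                "n": len(vals),
                "q1": q1,
                "median": med,
                "q3": q3,
                "whisker_low": lo,
                "whisker_high": hi,
            }
        )
    return pd.DataFrame(rows)
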