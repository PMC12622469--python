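"""Clinical-correlation statistics layer.

Covers the histology tubular-injury index (TII), assumption-dispatched
group comparisons (Shapiro-Wilk + Levene at alpha = 0.05 choose between
t-test / Mann-Whitney U, and ANOVA + Tukey / Kruskal-Wallis + Dunn with
Bonferroni), normality-dispatched Pearson/Spearman correlation, the
abundance-vs-clinical correlation matrix, urinary analyte-to-creatinine
normalization, and the differential-expression table filter
(|log2FC| > 1.5 and FDR < 0.05, both strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "score_tii",
    "tii_field_score",
    "compare_two_groups",
    "compare_multi_groups",
    "correlate",
    "abundance_clinical_matrix",
    "normalize_to_creatinine",
    "de_filter",
]

DISPATCH_ALPHA = 0.05
CLINICAL_VARS = ["serum_cr", "egfr", "crp", "tii", "cxcl9_urine", "cxcl9_serum"]


# ---------------------------------------------------------------------------
# tubular injury index
# ---------------------------------------------------------------------------


def tii_field_score(injured_fraction: float) -> int:
    """Map one high-power field's injured-tubule fraction to the 0-5 scale.

    0: no injury; 1: <10%; 2: 10-25%; 3: 26-50%; 4: 51-75%; 5: >75%.
    Boundaries between the verbal bins are closed so the scale is
    exhaustive: exactly 10% scores 2, exactly 25% scores 2, 50% scores 3,
    75% scores 4.
    """
    f = float(injured_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"injured fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return 0
    if f < 0.10:
        return 1
    if f <= 0.25:
        return 2
    if f <= 0.50:
        return 3
    if f <= 0.75:
        return 4
    return 5


def score_tii(injured_fractions, min_fields: int = 10) -> float:
    """Tubular injury index: mean field score over >= 10 high-power fields."""
    fracs = list(injured_fractions)
    if len(fracs) < min_fields:
        raise ValueError(
            f"TII requires at least {min_fields} scored fields, got {len(fracs)}"
        )
    return float(np.mean([tii_field_score(f) for f in fracs]))


# ---------------------------------------------------------------------------
# dispatched hypothesis tests
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Outcome of a group comparison plus its assumption diagnostics."""

    test_used: str
    statistic: float
    p: float
    direction: int  # sign of (first group's center - second's); 0 for multi-group
    shapiro_p: list[float] = field(default_factory=list)
    levene_p: float = float("nan")
    posthoc: pd.DataFrame | None = None
    degenerate: bool = False


def _normal_and_homoscedastic(groups: list[np.ndarray], alpha: float) -> tuple[list[float], float, bool]:
    shapiro_p = []
    for g in groups:
        if np.ptp(g) == 0:
            shapiro_p.append(0.0)  # constant sample: treat as non-normal
        else:
            shapiro_p.append(float(stats.shapiro(g).pvalue))
    if all(np.ptp(g) == 0 for g in groups):
        levene_p = 1.0
    else:
        levene_p = float(stats.levene(*groups).pvalue)
    ok = all(p > alpha for p in shapiro_p) and levene_p > alpha
    return shapiro_p, levene_p, ok


def compare_two_groups(
    x, y, paired: bool = False, alpha: float = DISPATCH_ALPHA, method: str = "auto"
) -> ComparisonResult:
    """Two-group comparison with normality/variance dispatch.

    Shapiro-Wilk per group and Levene across groups at ``alpha``; if all
    pass, an unpaired two-tailed t-test, otherwise a two-sided
    Mann-Whitney U (exact for n <= 20 per group without ties, normal
    approximation with tie correction otherwise). ``method`` overrides
    the dispatch: ``"t"`` or ``"mann-whitney"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    if paired and len(x) != len(y):
        raise ValueError("paired comparison needs equal lengths")

    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return ComparisonResult("degenerate", 0.0, 1.0, 0, [0.0, 0.0], 1.0, degenerate=True)

    shapiro_p, levene_p, parametric = _normal_and_homoscedastic([x, y], alpha)
    if method == "t":
        parametric = True
    elif method == "mann-whitney":
        parametric = False
    elif method != "auto":
        raise ValueError(f"unknown method {method!r}")
    direction = int(np.sign(np.mean(x) - np.mean(y)))
    if parametric:
        if paired:
            res = stats.ttest_rel(x, y)
            name = "t-paired"
        else:
            res = stats.ttest_ind(x, y, equal_var=True)
            name = "t"
        return ComparisonResult(name, float(res.statistic), float(res.pvalue),
                                direction, shapiro_p, levene_p)
    if paired:
        res = stats.wilcoxon(x, y)
        return ComparisonResult("wilcoxon", float(res.statistic), float(res.pvalue),
                                direction, shapiro_p, levene_p)
    small = max(len(x), len(y)) <= 20
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(x) - np.median(y)))
    return ComparisonResult("mann-whitney", float(res.statistic), float(res.pvalue),
                            direction, shapiro_p, levene_p)


def _dunn_bonferroni(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Pairwise Dunn z-tests on pooled mean ranks with tie correction,
    Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            rows.append(
                dict(group_a=names[i], group_b=names[j], z=float(z),
                     p=float(p), p_adj=float(min(1.0, p * m)))
            )
    return pd.DataFrame(rows)


def compare_multi_groups(
    groups: dict[str, np.ndarray] | list, alpha: float = DISPATCH_ALPHA
) -> ComparisonResult:
    """Multi-group comparison: ANOVA + Tukey HSD when parametric
    assumptions hold, Kruskal-Wallis + Dunn-Bonferroni otherwise."""
    if isinstance(groups, dict):
        names = list(groups.keys())
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        names = [f"g{i + 1}" for i in range(len(groups))]
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 3:
        raise ValueError("need >= 3 groups (use compare_two_groups for 2)")
    for nm, a in zip(names, arrays):
        if len(a) < 3:
            raise ValueError(f"group {nm!r} has n < 3")

    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        return ComparisonResult("degenerate", 0.0, 1.0, 0, [0.0] * len(arrays), 1.0,
                                degenerate=True)

    shapiro_p, levene_p, parametric = _normal_and_homoscedastic(arrays, alpha)
    if parametric:
        res = stats.f_oneway(*arrays)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(arrays)
        labels = np.concatenate([[nm] * len(a) for nm, a in zip(names, arrays)])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
        return ComparisonResult("anova+tukey", float(res.statistic), float(res.pvalue),
                                0, shapiro_p, levene_p, posthoc)
    res = stats.kruskal(*arrays)
    posthoc = _dunn_bonferroni(arrays, names)
    return ComparisonResult("kruskal-wallis+dunn-bonferroni", float(res.statistic),
                            float(res.pvalue), 0, shapiro_p, levene_p, posthoc)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def correlate(x, y, method: str = "auto", alpha: float = DISPATCH_ALPHA):
    """Correlation with normality dispatch.

    ``auto``: Pearson when both variables pass Shapiro-Wilk at ``alpha``,
    Spearman otherwise; explicit ``"pearson"``/``"spearman"`` honored.
    Returns (coefficient, p, method_used); a constant input yields
    (nan, nan, "undefined").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), "undefined"
    if method == "auto":
        px = stats.shapiro(x).pvalue
        py = stats.shapiro(y).pvalue
        method = "pearson" if (px > alpha and py > alpha) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), method


def abundance_clinical_matrix(
    abundances: pd.DataFrame,
    clinical: pd.DataFrame,
    clinical_vars: list[str] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Correlate every abundance column with every clinical covariate.

    ``abundances``: one row per sample_id, remaining columns are
    population densities or CN abundances. Missing clinical values are
    handled pairwise-complete, with the effective n reported per pair.
    """
    clinical_vars = clinical_vars or [c for c in CLINICAL_VARS if c in clinical.columns]
    merged = abundances.merge(clinical, on="sample_id", how="inner")
    feature_cols = [c for c in abundances.columns if c not in ("sample_id", "group")]
    rows = []
    for feat in feature_cols:
        for var in clinical_vars:
            sub = merged[[feat, var]].dropna()
            if len(sub) < 5 or sub[feat].nunique() == 1 or sub[var].nunique() == 1:
                rows.append(dict(feature=feat, clinical=var, r=np.nan, p=np.nan,
                                 method="undefined", n=len(sub)))
                continue
            r, p, used = correlate(sub[feat], sub[var], method=method)
            rows.append(dict(feature=feat, clinical=var, r=r, p=p, method=used, n=len(sub)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


def normalize_to_creatinine(analyte: float, creatinine: float) -> float:
    """Analyte concentration expressed per unit urinary creatinine."""
    if creatinine <= 0:
        raise ValueError("creatinine concentration must be positive")
    return float(analyte) / float(creatinine)


def de_filter(
    records: pd.DataFrame, fc_thresh: float = 1.5, fdr_thresh: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into up/down-regulated genes by strict thresholds.

    Keeps records with |log2fc| > fc_thresh AND fdr < fdr_thresh (both
    strict); the sign of log2fc routes the record to the upregulated or
    downregulated output.
    """
    lf = records["log2fc"].to_numpy(dtype=float)
    fdr = records["fdr"].to_numpy(dtype=float)
    keep = (np.abs(lf) > fc_thresh) & (fdr < fdr_thresh)
    up = records.loc[keep & (lf > 0)].copy()
    down = records.loc[keep & (lf < 0)].copy()
    return up, down
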