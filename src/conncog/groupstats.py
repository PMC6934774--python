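"""Per-node three-group statistics with assumption gating.

For each node and metric the three groups (HV, CP, CI) are compared with a
test chosen by two gates: Shapiro-Wilk normality per group, then Levene's
homogeneity of variances. Normal + homoscedastic data get one-way ANOVA with
Tukey HSD post-hoc; normal but heteroscedastic data get Welch's ANOVA with
pairwise Welch t-tests; any non-normal group routes to Kruskal-Wallis with
Dunn's post-hoc. Only the two contrasts of scientific interest are reported:
CP vs HV (disease effect) and CI vs CP (cognitive-status effect). P-values
are corrected across nodes within each metric x contrast family
(Benjamini-Hochberg by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.multitest import multipletests

from .graphmetrics import NodeMetricTable

__all__ = [
    "ContrastResult",
    "GroupComparisonResult",
    "StatsError",
    "CONTRASTS",
    "test_node",
    "correct_pvalues",
    "run_group_stats",
    "summarize_differences",
    "describe_cohort",
]

CONTRASTS = ("CP-HV", "CI-CP")


class StatsError(ValueError):
    """Invalid or degenerate statistical input."""


@dataclass
class ContrastResult:
    raw_p: float
    direction: int                  # sign of (second - first) group location
    corrected_p: float | None = None


@dataclass
class GroupComparisonResult:
    metric_name: str
    node_label: str
    omnibus_test: str               # anova | welch_anova | kruskal_wallis
    omnibus_p: float
    posthoc_test: str               # tukey_hsd | welch_t | dunn
    contrasts: dict[str, ContrastResult]


def _shapiro_p(x: np.ndarray) -> float:
    # A constant sample is maximally non-normal for gating purposes.
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def _dunn_pairs(
    samples: Sequence[np.ndarray], pairs: Sequence[tuple[int, int]]
) -> list[float]:
    """Dunn's rank-sum post-hoc z-tests with tie correction (two-sided)."""
    pooled = np.concatenate(samples)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    split = np.cumsum([s.size for s in samples])[:-1]
    group_ranks = np.split(ranks, split)
    mean_ranks = [gr.mean() for gr in group_ranks]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pvals = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / samples[a].size + 1.0 / samples[b].size))
        if se == 0:
            pvals.append(1.0)
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pvals.append(float(2.0 * stats.norm.sf(abs(z))))
    return pvals


@lru_cache(maxsize=64)
def _studentized_range_logsf_spline(k: int, df: int):
    # Exact sf evaluated once on a dense grid, then interpolated in log
    # space: |error| < 1e-4 on p, vastly cheaper than per-call quadrature.
    qs = np.linspace(0.0, _SR_QMAX, 281)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sf = stats.studentized_range.sf(qs, k, df)
    return PchipInterpolator(qs, np.log(np.clip(sf, 1e-300, 1.0)))


_SR_QMAX = 12.0


def _tukey_sf(q: float, k: int, df: float) -> float:
    """P(studentized range > q) with k groups and df error degrees of freedom."""
    if q <= 0:
        return 1.0
    if q >= _SR_QMAX:  # far tail: negligible and below any alpha in use
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.studentized_range.sf(q, k, df))
    spline = _studentized_range_logsf_spline(k, int(round(df)))
    return float(np.exp(spline(q)))


def _tukey_pairs(
    samples: Sequence[np.ndarray], pairs: Sequence[tuple[int, int]]
) -> list[float]:
    """Tukey HSD p-values for the requested pairs (balanced or unbalanced
    via the Tukey-Kramer standard error)."""
    k = len(samples)
    ns = np.array([s.size for s in samples])
    means = np.array([s.mean() for s in samples])
    df = int(ns.sum() - k)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
    out = []
    for a, b in pairs:
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(means[a] - means[b]) / se if se > 0 else 0.0
        out.append(min(1.0, _tukey_sf(q, k, df)))
    return out


def _welch_anova_p(samples: Sequence[np.ndarray]) -> float:
    import pingouin as pg

    df = pd.DataFrame(
        {
            "y": np.concatenate(samples),
            "g": np.repeat(np.arange(len(samples)), [s.size for s in samples]),
        }
    )
    res = pg.welch_anova(data=df, dv="y", between="g")
    pcol = "p_unc" if "p_unc" in res.columns else "p-unc"
    return float(res[pcol].iloc[0])


def test_node(
    values_by_group: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    alpha_gate: float = 0.05,
    metric_name: str = "",
    node_label: str = "",
) -> GroupComparisonResult:
    """Gated three-group comparison of one node's metric values.

    ``values_by_group`` holds the HV, CP and CI samples (in that order if a
    plain sequence). Directions are signs of differences in group means
    (parametric branches) or medians (rank branch): CP-HV and CI-CP.
    """
    if isinstance(values_by_group, Mapping):
        groups = [np.asarray(values_by_group[g], float) for g in ("HV", "CP", "CI")]
    else:
        groups = [np.asarray(g, float) for g in values_by_group]
    if len(groups) != 3:
        raise StatsError("expected exactly three group samples (HV, CP, CI)")
    if any(g.size < 3 for g in groups):
        raise StatsError("each group needs at least 3 observations")
    if np.ptp(np.concatenate(groups)) == 0:
        raise StatsError("values constant across all groups: nothing to test")

    pairs = [(0, 1), (1, 2)]  # CP-HV, CI-CP

    normal = all(_shapiro_p(g) >= alpha_gate for g in groups)
    if not normal:
        omnibus = "kruskal_wallis"
        posthoc = "dunn"
        omnibus_p = float(stats.kruskal(*groups).pvalue)
        raw = _dunn_pairs(groups, pairs)
        locs = [float(np.median(g)) for g in groups]
    else:
        levene_p = float(stats.levene(*groups).pvalue)
        locs = [float(np.mean(g)) for g in groups]
        if levene_p < alpha_gate:
            omnibus = "welch_anova"
            posthoc = "welch_t"
            omnibus_p = _welch_anova_p(groups)
            raw = [
                float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
                for a, b in pairs
            ]
        else:
            omnibus = "anova"
            posthoc = "tukey_hsd"
            omnibus_p = float(stats.f_oneway(*groups).pvalue)
            raw = _tukey_pairs(groups, pairs)

    contrasts = {}
    for (a, b), p, name in zip(pairs, raw, CONTRASTS):
        diff = locs[b] - locs[a]
        contrasts[name] = ContrastResult(raw_p=p, direction=int(np.sign(diff)))
    return GroupComparisonResult(
        metric_name, node_label, omnibus, omnibus_p, posthoc, contrasts
    )


def correct_pvalues(
    pvals: Sequence[float], method: str = "benjamini_hochberg"
) -> np.ndarray:
    """Multiple-comparison correction (BH step-up default, Bonferroni option)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    key = {"benjamini_hochberg": "fdr_bh", "bh": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in key:
        raise StatsError(f"unknown correction method '{method}'")
    return multipletests(p, method=key[method])[1]


def run_group_stats(
    metric_tables: Mapping[str, NodeMetricTable],
    groups: Sequence[str],
    alpha_gate: float = 0.05,
    correction: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Per-node gated tests for every metric, corrected across nodes.

    ``groups`` gives each subject's group aligned with the metric-table rows.
    Correction is applied across nodes within each metric x contrast family.
    Returns a long DataFrame: metric, node, omnibus_test, omnibus_p, contrast,
    raw_p, corrected_p, direction.
    """
    groups = np.asarray(groups)
    rows = []
    for metric, table in metric_tables.items():
        vals = table.values.to_numpy(dtype=float)
        results = []
        for j, node in enumerate(table.node_labels):
            samples = [vals[groups == g, j] for g in ("HV", "CP", "CI")]
            if np.ptp(np.concatenate(samples)) == 0:
                # constant node (e.g. degree when the mask fixes topology):
                # trivially non-significant rather than an error in batch mode
                results.append(
                    GroupComparisonResult(
                        metric, node, "degenerate", 1.0, "degenerate",
                        {c: ContrastResult(1.0, 0) for c in CONTRASTS},
                    )
                )
                continue
            results.append(
                test_node(samples, alpha_gate, metric_name=metric, node_label=node)
            )
        for contrast in CONTRASTS:
            raw = [r.contrasts[contrast].raw_p for r in results]
            corr = correct_pvalues(raw, correction)
            for r, cp in zip(results, corr):
                r.contrasts[contrast].corrected_p = float(cp)
        for r in results:
            for contrast in CONTRASTS:
                c = r.contrasts[contrast]
                rows.append(
                    {
                        "metric": metric,
                        "node": r.node_label,
                        "omnibus_test": r.omnibus_test,
                        "omnibus_p": r.omnibus_p,
                        "posthoc_test": r.posthoc_test,
                        "contrast": contrast,
                        "raw_p": c.raw_p,
                        "corrected_p": c.corrected_p,
                        "direction": c.direction,
                    }
                )
    return pd.DataFrame(rows)


def summarize_differences(
    stats_df: pd.DataFrame, alpha: float = 0.05, n_nodes: int | None = None
) -> pd.DataFrame:
    """Counts and percentages of significant nodes per metric x contrast.

    Nodes with corrected p < alpha are counted separately per direction;
    percentages are reported to one decimal, e.g. ``"42 (55.3%)"``.
    """
    out = []
    for (metric, contrast), grp in stats_df.groupby(["metric", "contrast"]):
        total = grp["node"].nunique()
        if n_nodes is not None and total != n_nodes:
            raise StatsError(
                f"{metric}/{contrast}: results cover {total} nodes, "
                f"expected {n_nodes}"
            )
        sig = grp[grp["corrected_p"] < alpha]
        for direction, label in ((-1, "decreased"), (1, "increased")):
            count = int((sig["direction"] == direction).sum())
            pct = round(100.0 * count / total, 1)
            out.append(
                {
                    "metric": metric,
                    "contrast": contrast,
                    "direction": label,
                    "count": count,
                    "percent": pct,
                    "display": f"{count} ({pct}%)",
                    "n_nodes": total,
                }
            )
    return pd.DataFrame(out)


def describe_cohort(subjects_df: pd.DataFrame) -> pd.DataFrame:
    """Cohort-description table: demographic group comparisons.

    Age across the three groups (gated ANOVA/Kruskal-Wallis), sex by
    chi-squared, and global cognition z between CP and CI. Purely
    descriptive; nothing downstream depends on it.
    """
    rows = []
    by_group = {g: subjects_df[subjects_df["group"] == g] for g in ("HV", "CP", "CI")}

    ages = [by_group[g]["age"].to_numpy(dtype=float) for g in ("HV", "CP", "CI")]
    if all(_shapiro_p(a) >= 0.05 for a in ages):
        test, p = "anova", float(stats.f_oneway(*ages).pvalue)
    else:
        test, p = "kruskal_wallis", float(stats.kruskal(*ages).pvalue)
    rows.append({"variable": "age", "test": test, "p": p})

    table = pd.crosstab(subjects_df["group"], subjects_df["sex"])
    chi2 = stats.chi2_contingency(table.to_numpy())
    rows.append({"variable": "sex", "test": "chi_squared", "p": float(chi2.pvalue)})

    cog_cols = [c for c in subjects_df.columns if c.startswith("cog_z_")]
    if cog_cols:
        gz = subjects_df[cog_cols].mean(axis=1)
        cp, ci = gz[subjects_df["group"] == "CP"], gz[subjects_df["group"] == "CI"]
        if len(cp) >= 3 and len(ci) >= 3:
            p = float(stats.mannwhitneyu(cp, ci).pvalue)
            rows.append({"variable": "global_z", "test": "mann_whitney", "p": p})
    return pd.DataFrame(rows)
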