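"""Joint polymorphism-expression inference.

The centrepiece is the diversity-matched resampling test for expression-
diversity (CV) loss in selection-candidate genes: outliers (by F_ST
percentile or low diversity ratio) are compared with null sets of
non-outlier genes drawn so each draw has equal or lower nucleotide
diversity than its matched outlier, which decouples the CV signal from the
diversity-CV correlation.  Around it: DE vs non-DE distribution summaries
with Kolmogorov-Smirnov tests, Fisher 2x2 enrichment, the chi-square test
for down-regulation bias, log-log polymorphism~expression regressions with
a pool interaction test, and the F_ST = 0 regulatory-only candidate list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutlierScan", "matched_resampling_test", "de_vs_nonde_distributions",
    "enrichment_2x2", "direction_bias_test",
    "polymorphism_expression_regression", "zero_fst_candidates",
]


@dataclass
class OutlierScan:
    """Result of one matched-resampling CV-loss test."""

    percentile: float
    cutoff: float
    outlier_genes: pd.Index
    observed_delta_cv: float
    cv_loss_fraction: float
    null_delta_cv: np.ndarray
    p_value: float
    n_relaxed: int = 0


def matched_resampling_test(
    cv_wild: pd.Series,
    cv_crop: pd.Series,
    pi: pd.Series,
    score: pd.Series,
    percentile: float = 95.0,
    n_resamples: int = 1000,
    rng: np.random.Generator | int | None = None,
    lower_tail: bool = False,
) -> OutlierScan:
    """Diversity-matched resampling test for CV loss in outlier genes.

    Outliers are genes with ``score`` (typically F_ST) at or above its
    ``percentile`` cutoff (or at/below, with ``lower_tail`` for ratio-based
    candidates).  Each of ``n_resamples`` null draws picks, for every
    outlier, one non-outlier gene uniformly among those with pi less than or
    equal to the outlier's pi (an outlier with no eligible donor relaxes to
    the nearest-pi donor, with a warning).  The empirical p-value is
    (1 + #{null mean(CVw - CVc) >= observed}) / (n_resamples + 1).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    data = pd.DataFrame({"cvw": cv_wild, "cvc": cv_crop, "pi": pi, "score": score}).dropna()
    if data.empty:
        raise ValueError("no genes with CV, pi and score all defined")
    cutoff = float(np.percentile(data["score"], percentile))
    out_mask = data["score"] <= cutoff if lower_tail else data["score"] >= cutoff
    outliers = data[out_mask]
    others = data[~out_mask].sort_values("pi")
    if outliers.empty or others.empty:
        raise ValueError("degenerate outlier split")
    dcv = (data["cvw"] - data["cvc"]).to_numpy()
    obs = float((outliers["cvw"] - outliers["cvc"]).mean())
    other_dcv = (others["cvw"] - others["cvc"]).to_numpy()
    other_pi = others["pi"].to_numpy()

    # eligible donors per outlier: all non-outliers with pi <= outlier pi
    n_elig = np.searchsorted(other_pi, outliers["pi"].to_numpy(), side="right")
    n_relaxed = int((n_elig == 0).sum())
    if n_relaxed:
        warnings.warn(f"{n_relaxed} outlier(s) had no donor with pi <= outlier pi; "
                      "relaxed to the nearest-pi donor")
    n_elig = np.maximum(n_elig, 1)
    draws = (rng.random((n_resamples, len(outliers))) * n_elig[None, :]).astype(np.int64)
    null = other_dcv[draws].mean(axis=1)
    p = (1.0 + float((null >= obs).sum())) / (n_resamples + 1.0)
    loss = obs / float(outliers["cvw"].mean()) if outliers["cvw"].mean() > 0 else float("nan")
    return OutlierScan(
        percentile=percentile, cutoff=cutoff, outlier_genes=outliers.index,
        observed_delta_cv=obs, cv_loss_fraction=loss, null_delta_cv=null,
        p_value=p, n_relaxed=n_relaxed,
    )


def de_vs_nonde_distributions(
    stats_table: pd.DataFrame,
    de_flags: pd.Series,
    columns: tuple[str, ...] = ("pi_s", "pi_n", "pin_pis", "tajimas_d", "ratio"),
    min_group: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries (mean/median/2.5-97.5 percentiles) of polymorphism statistics
    for DE vs non-DE genes, plus two-sample KS tests per statistic.  Tests
    are suppressed (nan) when either group has fewer than ``min_group``
    defined values."""
    de = de_flags.reindex(stats_table.index).fillna(False).astype(bool)
    summaries, tests = [], []
    for col in columns:
        if col not in stats_table:
            continue
        x = stats_table[col]
        for flag, name in ((de, "DE"), (~de, "non-DE")):
            v = x[flag].replace([np.inf, -np.inf], np.nan).dropna()
            summaries.append({
                "statistic": col, "group": name, "n": len(v),
                "mean": v.mean() if len(v) else np.nan,
                "median": v.median() if len(v) else np.nan,
                "q2.5": v.quantile(0.025) if len(v) else np.nan,
                "q97.5": v.quantile(0.975) if len(v) else np.nan,
            })
        a = x[de].replace([np.inf, -np.inf], np.nan).dropna()
        b = x[~de].replace([np.inf, -np.inf], np.nan).dropna()
        if len(a) >= min_group and len(b) >= min_group:
            ks = stats.ks_2samp(a, b)
            tests.append({"statistic": col, "ks_stat": ks.statistic, "ks_p": ks.pvalue,
                          "n_de": len(a), "n_nonde": len(b)})
        else:
            tests.append({"statistic": col, "ks_stat": np.nan, "ks_p": np.nan,
                          "n_de": len(a), "n_nonde": len(b)})
    return pd.DataFrame(summaries), pd.DataFrame(tests)


def enrichment_2x2(
    flags_a: pd.Series | np.ndarray,
    flags_b: pd.Series | np.ndarray,
    alternative: str = "two-sided",
) -> dict:
    """Fisher's exact test of association between two binary gene flags.

    Returns the 2x2 table, the sample odds ratio (Haldane 0.5 correction
    when a cell is zero) and the hypergeometric point-probability p-value.
    Degenerate margins give p = 1.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must align")
    table = np.array([
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return {"table": table, "odds_ratio": np.nan, "p": 1.0}
    t = table.astype(float)
    if (table == 0).any():
        t = t + 0.5
    orat = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, p = stats.fisher_exact(table, alternative=alternative)
    return {"table": table, "odds_ratio": float(orat), "p": float(p)}


def direction_bias_test(de_flags: pd.Series, logfc: pd.Series, min_de: int = 10) -> dict:
    """Is the crop-down fraction among DE genes biased relative to the whole
    gene set?  logFC is log2(wild/crop), so logFC > 0 = down-regulated in
    the crop.  Uses a 2x2 chi-square (DE x direction); small DE sets fall
    back to an exact binomial test against the background down-fraction."""
    de = de_flags.astype(bool)
    down = logfc > 0
    n_de = int(de.sum())
    if n_de == 0:
        raise ValueError("DE set is empty")
    frac_de = float(down[de].mean())
    frac_all = float(down.mean())
    if n_de < min_de:
        p = stats.binomtest(int(down[de].sum()), n_de, frac_all).pvalue
        method = "binomial"
    else:
        table = np.array([
            [int(down[de].sum()), int((~down[de]).sum())],
            [int(down[~de].sum()), int((~down[~de]).sum())],
        ])
        p = stats.chi2_contingency(table, correction=False).pvalue
        method = "chi2"
    return {"frac_down_de": frac_de, "frac_down_all": frac_all, "n_de": n_de,
            "p": float(p), "method": method}


def polymorphism_expression_regression(
    stat: pd.Series,
    expression: pd.Series,
    pools: pd.Series,
    min_genes: int = 10,
) -> dict:
    """Log-log regression of a polymorphism statistic on mean expression.

    ``stat``/``expression``/``pools`` are aligned per (gene x pool) rows.
    Per pool: OLS of log10(stat) on log10(expression) (slope, adjusted R2,
    slope p).  Pooled: log-expression x pool interaction F-test (does the
    slope differ between wild and crop?).  Only rows with positive values
    enter (log-transformable).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"stat": stat, "expr": expression, "pool": pools}).dropna()
    df = df[(df["stat"] > 0) & (df["expr"] > 0)]
    if len(df) < min_genes:
        raise ValueError(f"fewer than {min_genes} usable genes")
    df["y"] = np.log10(df["stat"])
    df["x"] = np.log10(df["expr"])
    out: dict = {"per_pool": {}}
    for pool, sub in df.groupby("pool"):
        if len(sub) < min_genes:
            continue
        fit = sm.OLS(sub["y"], sm.add_constant(sub["x"])).fit()
        out["per_pool"][pool] = {
            "slope": float(fit.params["x"]),
            "adj_r2": float(fit.rsquared_adj),
            "p": float(fit.pvalues["x"]),
            "n": int(len(sub)),
        }
    if df["pool"].nunique() > 1:
        full = smf.ols("y ~ x * C(pool)", data=df).fit()
        reduced = smf.ols("y ~ x + C(pool)", data=df).fit()
        ftest = full.compare_f_test(reduced)
        out["interaction"] = {"f": float(ftest[0]), "p": float(ftest[1]), "df": float(ftest[2])}
    return out


def zero_fst_candidates(de_flags: pd.Series, fst: pd.Series) -> pd.DataFrame:
    """DE genes with F_ST <= 0: expression divergence without measurable
    sequence differentiation ("regulatory-only" domestication candidates)."""
    de = de_flags.astype(bool)
    sel = de & (fst <= 0) & fst.notna()
    return pd.DataFrame({
        "gene_id": sel.index[sel],
        "fst": fst[sel].to_numpy(),
        "annotation": "regulatory-only candidate",
    })
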