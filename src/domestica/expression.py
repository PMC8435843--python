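"""Count-matrix processing: CPM filtering, TMM normalization, per-pool
coefficient of variation, two-group negative-binomial exact tests with
Benjamini-Hochberg FDR, and expression PCA.

The differential-expression route follows the classic exact-test workflow:
counts are quantile-adjusted to a common effective library size, a common NB
dispersion is estimated by conditional maximum likelihood, and each gene is
tested by conditioning on its per-group pseudo-count totals.  The log fold
change is reported as log2(wild/crop), so genes down-regulated in the
domesticated pool have positive logFC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binomtest

from .popgen import CROP, WILD

__all__ = [
    "ExpressionTable", "cpm", "filter_expressed", "tmm_factors",
    "estimate_common_dispersion", "exact_test_de", "expression_cv",
    "expression_pca", "bh_adjust",
]


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; library sizes default to column sums."""
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    return counts / lib * 1e6


def filter_expressed(
    counts: pd.DataFrame,
    labels: pd.Series,
    min_accessions: int = 5,
    min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_accessions``
    accessions (CPM on raw library sizes).  The permissive "in at least five
    accessions" reading is used; tighten by raising ``min_accessions``."""
    missing = set(counts.columns) - set(labels.index)
    if missing:
        raise ValueError(f"accessions without pool labels: {sorted(missing)}")
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_accessions
    out = counts.loc[keep]
    if out.empty:
        import warnings

        warnings.warn("no genes pass the expression filter")
    return out


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (Robinson & Oshlack
    2010): doubly trimmed, inverse-variance-weighted mean of M values."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    p_obs = obs[ok] / n_obs
    p_ref = ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any() or not np.isfinite(m[keep]).any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    q75 = np.array([np.quantile(x[:, j][x[:, j] > 0] / lib[j], 0.75) if (x[:, j] > 0).any() else 0.0
                    for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([
        1.0 if j == ref_idx else _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


def _cond_loglik(y: np.ndarray, r: float) -> float:
    """Conditional (on the row sum) NB log-likelihood for equal-mean samples;
    the Dirichlet-multinomial form used in qCML dispersion estimation."""
    n = y.shape[1]
    s = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(s + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    pseudo: np.ndarray, groups: list[np.ndarray], min_phi: float = 1e-6, max_phi: float = 10.0
) -> float:
    """Common NB dispersion maximizing the conditional likelihood summed over
    genes and groups (pseudo-counts assumed on a common library size)."""
    mats = [np.round(pseudo[:, g]) for g in groups if g.size >= 2]
    mats = [m[m.sum(axis=1) > 0] for m in mats]

    def neg(logphi: float) -> float:
        r = 1.0 / np.exp(logphi)
        return -sum(_cond_loglik(m, r) for m in mats)

    res = minimize_scalar(neg, bounds=(np.log(min_phi), np.log(max_phi)), method="bounded",
                          options={"xatol": 1e-4})
    phi = float(np.exp(res.x))
    if phi <= min_phi * 1.5 and neg(np.log(min_phi)) <= res.fun:
        return 0.0
    return phi


def _q2q_normal(x: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: float) -> np.ndarray:
    """Quantile adjustment of NB counts to a new mean by normal moment
    matching (mean/variance of NB(mu, phi) -> NB(mu', phi))."""
    v_in = mu_in + phi * mu_in**2
    v_out = mu_out + phi * mu_out**2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x + 0.5 - mu_in) / np.sqrt(np.maximum(v_in, 1e-300))
    return np.clip(mu_out + z * np.sqrt(v_out) - 0.5, 0.0, None)


def _exact_nb_pvalue(y1: int, s: int, r1: float, r2: float) -> float:
    """Two-sided conditional exact NB p-value: the probability mass of all
    split outcomes y of the total s with P(y) <= P(y1) (beta-binomial
    conditional distribution of the group-1 total)."""
    y = np.arange(s + 1)
    logp = (
        gammaln(y + r1) - gammaln(y + 1)
        + gammaln(s - y + r2) - gammaln(s - y + 1)
    )
    logp -= logsumexp(logp)
    return float(np.exp(logsumexp(logp[logp <= logp[y1] + 1e-10])))


def exact_test_de(
    counts: pd.DataFrame,
    labels: pd.Series,
    fdr: float = 0.01,
    dispersion: float | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Gene-wise two-group NB exact tests with BH correction.

    Returns a per-gene frame with logFC (log2 wild/crop), the exact-test
    p-value, the BH q-value and the DE flag at the requested FDR.  A fitted
    dispersion of ~0 falls back to the Poisson (binomial split) exact test.
    """
    pools = labels.reindex(counts.columns)
    g_wild = np.flatnonzero((pools == WILD).to_numpy())
    g_crop = np.flatnonzero((pools == CROP).to_numpy())
    if g_wild.size < 2 or g_crop.size < 2:
        raise ValueError("need at least 2 accessions per pool")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    eff = lib * tmm_factors(counts).to_numpy()
    common = float(np.exp(np.mean(np.log(eff))))

    # abundance per gene, then quantile-adjust counts to the common size
    rate = x.sum(axis=1) / eff.sum()
    phi = 0.1 if dispersion is None else dispersion
    pseudo = x
    for _ in range(2):
        pseudo = _q2q_normal(x, np.outer(rate, eff), np.outer(rate, np.full_like(eff, common)), phi)
        if dispersion is None:
            phi = estimate_common_dispersion(pseudo, [g_wild, g_crop])
        else:
            break
    pseudo_r = np.round(pseudo).astype(np.int64)

    s1 = pseudo_r[:, g_wild].sum(axis=1)
    s2 = pseudo_r[:, g_crop].sum(axis=1)
    n1, n2 = g_wild.size, g_crop.size
    pvals = np.ones(len(x))
    for i in range(len(x)):
        s = int(s1[i] + s2[i])
        if s == 0:
            continue
        if phi > 0:
            pvals[i] = _exact_nb_pvalue(int(s1[i]), s, n1 / phi, n2 / phi)
        else:
            bt = binomtest(int(s1[i]), s, n1 / (n1 + n2))
            pvals[i] = bt.pvalue
    qvals = bh_adjust(pvals)
    logfc = np.log2((s1 / n1 + prior_count) / (s2 / n2 + prior_count))
    return pd.DataFrame(
        {
            "logfc": logfc,
            "p": pvals,
            "q": qvals,
            "de": qvals <= fdr,
            "mean_pseudo_wild": s1 / n1,
            "mean_pseudo_crop": s2 / n2,
            "dispersion": phi,
        },
        index=counts.index,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p-rank)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def expression_cv(
    counts: pd.DataFrame, labels: pd.Series, lib_sizes: pd.Series | None = None,
    tmm: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene coefficient of variation (sample sd / mean) of TMM-normalized
    CPM within each pool; nan for zero-mean genes."""
    if tmm is None:
        tmm = tmm_factors(counts)
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    norm = cpm(counts, lib * tmm)
    pools = labels.reindex(counts.columns)
    out = {}
    for pool in (WILD, CROP):
        sub = norm.loc[:, (pools == pool).to_numpy()]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"cv_{pool}"] = (sd / mean).where(mean > 0)
        out[f"mean_cpm_{pool}"] = mean
    return pd.DataFrame(out, index=counts.index)


def expression_pca(
    counts: pd.DataFrame, tmm: pd.Series | None = None, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of accessions on log2(CPM + 1) of TMM-normalized counts, with the
    same centering/sign conventions as the genotype PCA."""
    from .popgen import genotype_pca

    if tmm is None:
        tmm = tmm_factors(counts)
    norm = np.log2(cpm(counts, counts.sum(axis=0) * tmm) + 1.0)
    coords, varexp = genotype_pca(norm.to_numpy().T, n_components=n_components)
    frame = pd.DataFrame(
        coords, index=counts.columns,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    return frame, varexp


@dataclass
class ExpressionTable:
    """Bundled expression results for one dataset."""

    counts: pd.DataFrame
    labels: pd.Series
    lib_sizes: pd.Series = field(init=False)
    tmm: pd.Series = field(init=False)
    results: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.lib_sizes = self.counts.sum(axis=0)
        self.tmm = tmm_factors(self.counts)

    def cpm(self, normalized: bool = True) -> pd.DataFrame:
        lib = self.lib_sizes * self.tmm if normalized else self.lib_sizes
        return cpm(self.counts, lib)

    def analyze(self, fdr: float = 0.01) -> pd.DataFrame:
        de = exact_test_de(self.counts, self.labels, fdr=fdr)
        cv = expression_cv(self.counts, self.labels, tmm=self.tmm)
        self.results = de.join(cv)
        return self.results
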