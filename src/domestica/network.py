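"""Signed weighted co-expression network analysis.

Pipeline: Pearson correlation of log2(CPM+1) profiles across accessions ->
signed similarity s = (1 + cor)/2 -> soft-threshold adjacency a = s^beta
(beta picked from the scale-free topology fit or fixed, the emulated study
fixed beta = 20) -> topological overlap matrix (TOM) -> average-linkage
clustering of 1 - TOM with a simplified recursive tree cut -> module
eigengenes -> merging of modules whose eigengenes are closer than the merge
height -> Fisher enrichment of modules in gene flags.

The tree cut is deliberately simpler than WGCNA's dynamic hybrid: a static
cut followed by recursive gap-based splitting, plus a cohesion requirement
(mean intra-cluster TOM at least ``cohesion`` times the mean TOM between
the cluster and the rest) that sends incoherent clusters to the unassigned
label 0.  Acceptance is planted-module recovery, not WGCNA label identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import bh_adjust

__all__ = [
    "ModuleSet", "log_cpm", "signed_similarity", "pick_soft_power",
    "build_tom", "detect_modules", "module_eigengene", "module_enrichment",
    "outlier_accession_report",
]


def log_cpm(counts: pd.DataFrame, tmm: pd.Series | None = None) -> pd.DataFrame:
    """log2(CPM + 1) on TMM-normalized library sizes (genes x accessions)."""
    from .expression import cpm, tmm_factors

    if tmm is None:
        tmm = tmm_factors(counts)
    return np.log2(cpm(counts, counts.sum(axis=0) * tmm) + 1.0)


def signed_similarity(expr: np.ndarray) -> np.ndarray:
    """Signed similarity (1 + cor)/2 between gene expression profiles
    (rows); maps cor -1 -> 0, 0 -> 0.5, +1 -> 1.  Constant genes get
    similarity 0.5 to everything (correlation treated as 0)."""
    x = np.asarray(expr, dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    cor = np.zeros((x.shape[0], x.shape[0]))
    if ok.sum() >= 2:
        cor[np.ix_(ok, ok)] = np.corrcoef(x[ok])
    np.fill_diagonal(cor, 1.0)
    return (1.0 + np.clip(cor, -1.0, 1.0)) / 2.0


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit R^2 and slope from the log10 p(k) vs
    log10 k regression over connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return float("nan"), float("nan")
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(np.sign(-slope) * r**2), float(slope)


def pick_soft_power(
    expr: np.ndarray,
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    rsq_cut: float = 0.8,
    fixed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power beta for a signed network.

    For each candidate: adjacency ((1+cor)/2)^beta, connectivity k, and the
    signed scale-free fit R^2.  Returns the smallest power reaching
    ``rsq_cut`` (or the best-fitting power if none does), plus the fit
    table.  ``fixed`` bypasses the scan and is returned untouched.
    """
    if fixed is not None:
        return int(fixed), pd.DataFrame()
    s = signed_similarity(expr)
    rows = []
    for beta in candidate_powers:
        a = s**beta
        k = a.sum(axis=0) - 1.0
        r2, slope = _scale_free_fit(k)
        rows.append({"power": beta, "sft_r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k)),
                     "max_k": float(k.max())})
    fits = pd.DataFrame(rows)
    good = fits[fits["sft_r2"] >= rsq_cut]
    if len(good):
        beta = int(good["power"].iloc[0])
    else:
        beta = int(fits.loc[fits["sft_r2"].idxmax(), "power"])
    return beta, fits


def build_tom(expr: np.ndarray, beta: int = 20, similarity: np.ndarray | None = None) -> np.ndarray:
    """Topological overlap dissimilarity 1 - TOM of the signed network.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    the diagonal of TOM set to 1.
    """
    if similarity is None:
        if expr.shape[0] < 2:
            raise ValueError("need at least 2 genes")
        similarity = signed_similarity(expr)
    a = similarity**beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def module_eigengene(expr: np.ndarray) -> np.ndarray:
    """First principal component of a module's standardized expression
    (samples-long, unit norm), oriented to correlate positively with the
    module mean expression."""
    x = np.asarray(expr, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_prof = z.mean(axis=0)
    if np.dot(e, mean_prof) < 0:
        e = -e
    return e / np.linalg.norm(e)


def _cohesive(diss: np.ndarray, idx: np.ndarray, cohesion: float, background_tom: float) -> bool:
    """A cluster is a module only if its mean intra-cluster TOM exceeds
    ``cohesion`` times the network-wide mean TOM (incoherent clusters --
    e.g. the bulk of unconnected genes -- sit at the background level)."""
    n = idx.size
    if n < 2:
        return False
    tom_in = 1.0 - diss[np.ix_(idx, idx)]
    intra = (tom_in.sum() - n) / (n * (n - 1))
    return intra > cohesion * background_tom


def _intra_tom(diss: np.ndarray, idx: np.ndarray) -> float:
    n = idx.size
    if n < 2:
        return 0.0
    return float(((1.0 - diss[np.ix_(idx, idx)]).sum() - n) / (n * (n - 1)))


def _recursive_split(diss: np.ndarray, idx: np.ndarray, min_size: int, gap: float) -> list[np.ndarray]:
    """Split a cluster at its top merge when (a) the merge height steps up
    by more than ``gap`` over the taller child subtree, or (b) the tighter
    half is substantially more cohesive than the parent (distinct modules
    glued together by interleaved background genes).  Over-splitting of a
    homogeneous module is undone later by eigengene merging."""
    if idx.size < max(2 * min_size, 4):
        return [idx]
    sub = diss[np.ix_(idx, idx)]
    z = linkage(squareform(sub, checks=False), method="average")
    m = idx.size
    child_heights = [z[int(c) - m, 2] if int(c) >= m else 0.0 for c in z[-1, :2]]
    labels2 = fcluster(z, t=2, criterion="maxclust")
    parts = [idx[labels2 == c] for c in (1, 2)]
    gap_split = z[-1, 2] - max(child_heights) > gap
    parent_tom = _intra_tom(diss, idx)
    quality_split = max(_intra_tom(diss, p) for p in parts) > 1.3 * parent_tom
    small, big = sorted(parts, key=lambda p: p.size)
    if not (gap_split or quality_split):
        if small.size < min_size and big.size >= 2 * min_size:
            # top merge only peels a satellite; descend into the main body
            return [small] + _recursive_split(diss, big, min_size, gap)
        return [idx]
    out = []
    for part in parts:
        if part.size >= min_size:
            out.extend(_recursive_split(diss, part, min_size, gap))
        else:
            out.append(part)
    return out


@dataclass
class ModuleSet:
    """Module detection result: per-gene labels (0 = unassigned, modules
    numbered by decreasing size), eigengenes and bookkeeping."""

    beta: int
    labels: np.ndarray
    eigengenes: pd.DataFrame  # samples x modules
    merge_height: float
    min_module_size: int
    sizes: dict[int, int] = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None

    @property
    def n_modules(self) -> int:
        return int((np.unique(self.labels) > 0).sum())


def detect_modules(
    diss_tom: np.ndarray,
    expr: np.ndarray,
    beta: int = 20,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    static_cut_quantile: float = 0.90,
    split_gap: float = 0.05,
    cohesion: float = 2.0,
    sample_names: list[str] | None = None,
) -> ModuleSet:
    """Average-linkage clustering of the TOM dissimilarity with a simplified
    recursive tree cut, cohesion filtering, eigengene computation, and
    merging of modules with eigengene dissimilarity below ``merge_height``.

    Deterministic given the data (no randomness anywhere in the path).
    """
    n = diss_tom.shape[0]
    labels = np.zeros(n, dtype=int)
    if min_module_size > n:
        return ModuleSet(beta, labels, pd.DataFrame(), merge_height, min_module_size)
    z = linkage(squareform(diss_tom, checks=False), method="average")
    cut = float(np.quantile(z[:, 2], static_cut_quantile))
    coarse = fcluster(z, t=cut, criterion="distance")
    clusters: list[np.ndarray] = []
    for c in np.unique(coarse):
        idx = np.flatnonzero(coarse == c)
        if idx.size < min_module_size:
            continue
        clusters.extend(_recursive_split(diss_tom, idx, min_module_size, split_gap))
    background = float((1.0 - diss_tom).sum() - n) / (n * (n - 1))
    modules = [c for c in clusters
               if c.size >= min_module_size and _cohesive(diss_tom, c, cohesion, background)]
    if not modules:
        import warnings

        warnings.warn("no cohesive module found; all genes unassigned")
        return ModuleSet(beta, labels, pd.DataFrame(), merge_height, min_module_size)

    # eigengene merging
    def eig(idx: np.ndarray) -> np.ndarray:
        return module_eigengene(expr[idx])

    eigs = [eig(c) for c in modules]
    while len(modules) > 1:
        e = np.array(eigs)
        cor = np.corrcoef(e)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_height:
            break
        merged = np.concatenate([modules[i], modules[j]])
        keep = [k for k in range(len(modules)) if k not in (i, j)]
        modules = [modules[k] for k in keep] + [merged]
        eigs = [eigs[k] for k in keep] + [eig(merged)]

    order = np.argsort([-c.size for c in modules], kind="stable")
    sizes = {}
    eig_cols = {}
    for rank, k in enumerate(order, start=1):
        labels[modules[k]] = rank
        sizes[rank] = int(modules[k].size)
        eig_cols[f"module_{rank}"] = eigs[k]
    index = sample_names if sample_names is not None else list(range(expr.shape[1]))
    eigengenes = pd.DataFrame(eig_cols, index=index)
    return ModuleSet(beta, labels, eigengenes, merge_height, min_module_size, sizes)


def module_enrichment(
    modules: ModuleSet,
    flags: pd.Series | np.ndarray,
    expr: np.ndarray | None = None,
    pools: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fisher 2x2 enrichment of each module in a binary gene flag, with BH
    correction across modules; optionally reports each module's mean
    expression direction in the crop pool (up/down vs wild)."""
    from .selection import enrichment_2x2

    flags = np.asarray(flags, dtype=bool)
    rows = []
    for m in sorted(k for k in np.unique(modules.labels) if k > 0):
        in_mod = modules.labels == m
        res = enrichment_2x2(in_mod, flags)
        row = {"module": m, "size": int(in_mod.sum()),
               "n_flagged": int((in_mod & flags).sum()),
               "odds_ratio": res["odds_ratio"], "p": res["p"]}
        if expr is not None and pools is not None:
            wild = pools == "wild"
            delta = expr[in_mod][:, ~wild].mean() - expr[in_mod][:, wild].mean()
            row["direction_crop"] = "down" if delta < 0 else "up"
            row["mean_log_expr_delta_crop"] = float(delta)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def outlier_accession_report(
    modules: ModuleSet, pools: pd.Series, z_cut: float = 2.5
) -> pd.DataFrame:
    """Per accession x module eigengene score with its z-score within the
    accession's pool; accessions with |z| > ``z_cut`` in a module are
    flagged as expression outliers."""
    rows = []
    for col in modules.eigengenes.columns:
        e = modules.eigengenes[col]
        for pool, sub in e.groupby(pools.reindex(e.index)):
            mu, sd = sub.mean(), sub.std(ddof=1)
            for acc, val in sub.items():
                z = (val - mu) / sd if sd > 0 else 0.0
                rows.append({"accession": acc, "pool": pool, "module": col,
                             "eigengene": float(val), "z": float(z),
                             "flagged": bool(abs(z) > z_cut)})
    return pd.DataFrame(rows, columns=["accession", "pool", "module",
                                       "eigengene", "z", "flagged"])
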