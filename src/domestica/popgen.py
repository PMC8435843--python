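"""Per-gene population-genetic statistics for two pools (wild vs crop).

Works on per-gene haplotype alignments of diploid accessions (two haplotype
rows per accession).  Within-pool statistics: nucleotide diversity pi
(unbiased average pairwise difference per site), synonymous/nonsynonymous
diversity via Nei-Gojobori (1986) site counting, Tajima's D, and the
inbreeding coefficient F = 1 - Hobs/Hexp.  Between pools: Hudson's (1992)
F_ST as a ratio of sums over sites, and the diversity ratio
r = pi_crop/pi_wild with its selection classification.

Missing genotypes are coded as base 4 (see codons.MISSING); every statistic
uses per-site sample sizes so partially-called sites remain informative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .codons import MISSING, SYN_DIFFS, SYN_SITES, NONSYN_DIFFS, NONSYN_SITES, encode_codons

WILD = "wild"
CROP = "crop"

#: selection classes for the pi_crop/pi_wild ratio
SWEEP_CANDIDATE = "sweep_candidate"
REDUCED = "reduced"
BASELINE = "baseline"
ELEVATED = "elevated"
UNDEFINED = "undefined"


@dataclass
class GenePool:
    """Haplotype alignment of one gene in one pool.

    ``haplotypes`` is a (2 * n_accessions, L) uint8 matrix with A,C,G,T ->
    0..3 and missing -> 4; rows 2i and 2i+1 are the two haplotypes of
    accession i.  ``frame_offset`` is the 0-based offset of the first
    complete codon.
    """

    gene_id: str
    pool: str
    accessions: list[str]
    haplotypes: np.ndarray
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2 * len(self.accessions):
            raise ValueError("haplotypes must be a (2*n_accessions, L) matrix")

    @property
    def n_ind(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def coding(self) -> np.ndarray:
        """Alignment trimmed to complete codons."""
        L = self.n_sites - self.frame_offset
        return self.haplotypes[:, self.frame_offset : self.frame_offset + 3 * (L // 3)]

    def called_individuals(self) -> np.ndarray:
        """(n_ind, L) bool: accession has both haplotypes called at site."""
        h = self.haplotypes.reshape(self.n_ind, 2, -1)
        return (h < MISSING).all(axis=1)


def allele_counts(haplotypes: np.ndarray) -> np.ndarray:
    """(4, L) per-site counts of each base over called haplotypes."""
    return np.stack([(haplotypes == b).sum(axis=0) for b in range(4)])


def site_pi(haplotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site diversity and per-site called-haplotype counts.

    The per-site value is the mean pairwise difference over all pairs of
    called haplotypes, i.e. (1 - sum p^2) * n/(n-1); nan where n < 2.
    """
    counts = allele_counts(haplotypes)
    n = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (n.astype(float) ** 2 - (counts.astype(float) ** 2).sum(axis=0)) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi, n


def filter_sites(
    wild: GenePool, crop: GenePool, min_called_per_pool: int = 5
) -> tuple[GenePool, GenePool, dict]:
    """Drop sites called in fewer than ``min_called_per_pool`` individuals in
    either pool, then drop every codon that lost a position (so the output
    stays in frame).  Returns the filtered pair plus an info dict with the
    kept-site index and an ``empty`` flag (never raises on empty genes)."""
    if wild.n_sites != crop.n_sites:
        raise ValueError("pools must share the site coordinate system")
    keep = (wild.called_individuals().sum(axis=0) >= min_called_per_pool) & (
        crop.called_individuals().sum(axis=0) >= min_called_per_pool
    )
    # codon bookkeeping: a codon survives only if all three positions do
    off = wild.frame_offset
    codon_keep = keep.copy()
    L = wild.n_sites
    ncod = (L - off) // 3
    codons = keep[off : off + 3 * ncod].reshape(ncod, 3).all(axis=1)
    codon_keep[:off] = False
    codon_keep[off : off + 3 * ncod] = np.repeat(codons, 3)
    codon_keep[off + 3 * ncod :] = False
    idx = np.flatnonzero(codon_keep)
    info = {"kept_sites": idx, "n_removed": int(L - idx.size), "empty": idx.size == 0}
    w = replace(wild, haplotypes=wild.haplotypes[:, idx], frame_offset=0)
    c = replace(crop, haplotypes=crop.haplotypes[:, idx], frame_offset=0)
    return w, c, info


def pi(gene: GenePool) -> float:
    """Per-site nucleotide diversity (nan when no site has >= 2 calls)."""
    sp, _n = site_pi(gene.haplotypes)
    used = ~np.isnan(sp)
    if not used.any():
        return float("nan")
    return float(np.nanmean(sp))


def pi_syn_nonsyn(gene: GenePool) -> tuple[float, float, float]:
    """Nei-Gojobori synonymous and nonsynonymous diversity (piS, piN, piN/piS).

    Differences and NG86 site counts are accumulated over all haplotype
    pairs (ratio of sums), skipping codons with missing data or stops for
    that pair; multi-hit codons average over valid mutational pathways.
    piN/piS is nan when piS = 0 or no codon is comparable.
    """
    C = encode_codons(gene.coding())
    n = C.shape[0]
    sd = nd = ss = ns = 0.0
    flat_syn = SYN_DIFFS.ravel()
    flat_non = NONSYN_DIFFS.ravel()
    for i in range(n - 1):
        ci = C[i]
        for j in range(i + 1, n):
            cj = C[j]
            ok = (ci >= 0) & (cj >= 0)
            if not ok.any():
                continue
            a, b = ci[ok], cj[ok]
            k = a * 64 + b
            sd += flat_syn[k].sum()
            nd += flat_non[k].sum()
            ss += 0.5 * (SYN_SITES[a] + SYN_SITES[b]).sum()
            ns += 0.5 * (NONSYN_SITES[a] + NONSYN_SITES[b]).sum()
    pis = sd / ss if ss > 0 else float("nan")
    pin = nd / ns if ns > 0 else float("nan")
    ratio = pin / pis if pis and pis > 0 else float("nan")
    return pis, pin, ratio


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled haplotypes."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_summary(kbar: float, S: int, n: int) -> float:
    """Tajima's D from the mean pairwise difference count kbar, the number
    of segregating sites S, and the haplotype sample size n."""
    if S < 1 or n < 4:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((kbar - S / c["a1"]) / np.sqrt(var))


def tajimas_d(gene: GenePool) -> float:
    """Tajima's D; nan when S = 0 or fewer than 4 haplotypes are usable.

    With missing data, n is the median per-site called-haplotype count and
    the pairwise-difference total is the sum of per-site unbiased values
    over the callable sites.
    """
    sp, ncalls = site_pi(gene.haplotypes)
    used = ~np.isnan(sp)
    if not used.any():
        return float("nan")
    counts = allele_counts(gene.haplotypes)
    seg = ((counts > 0).sum(axis=0) >= 2) & used
    S = int(seg.sum())
    n = int(np.median(ncalls[used]))
    k = float(sp[used].sum())  # mean pairwise differences over the gene
    return tajimas_d_from_summary(k, S, n)


def _het_sums(gene: GenePool) -> tuple[float, float]:
    """Summed observed and expected heterozygosity over polymorphic sites."""
    h = gene.haplotypes.reshape(gene.n_ind, 2, -1)
    called = (h < MISSING).all(axis=1)
    nc = called.sum(axis=0)
    het = ((h[:, 0, :] != h[:, 1, :]) & called).sum(axis=0)
    masked = np.where(called[:, None, :], h, MISSING).reshape(2 * gene.n_ind, -1)
    counts = allele_counts(masked)
    ntot = counts.sum(axis=0).astype(float)
    poly = ((counts > 0).sum(axis=0) >= 2) & (nc >= 2)
    if not poly.any():
        return 0.0, 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = (counts.astype(float) ** 2).sum(axis=0) / ntot**2
        hexp = (ntot / (ntot - 1.0)) * (1.0 - p2)
        hobs = het / nc
    return float(hobs[poly].sum()), float(hexp[poly].sum())


def fixation_index(
    genes: GenePool | list[GenePool],
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Inbreeding coefficient F = 1 - sum(Hobs)/sum(Hexp) over polymorphic
    sites, aggregated across genes; optional percentile bootstrap over genes.
    Returns (F, ci) with F nan when no polymorphic site exists."""
    if isinstance(genes, GenePool):
        genes = [genes]
    pairs = np.array([_het_sums(g) for g in genes], dtype=float)
    ho, he = pairs.sum(axis=0)
    f = 1.0 - ho / he if he > 0 else float("nan")
    ci = None
    if n_bootstrap and np.isfinite(f):
        rng = rng or np.random.default_rng()
        idx = rng.integers(0, len(genes), size=(n_bootstrap, len(genes)))
        bho = pairs[idx, 0].sum(axis=1)
        bhe = pairs[idx, 1].sum(axis=1)
        ok = bhe > 0
        boots = 1.0 - bho[ok] / bhe[ok]
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return f, ci


def fst(wild: GenePool, crop: GenePool) -> float:
    """Hudson's F_ST as 1 - sum(Hw)/sum(Hb) over sites callable (>= 2
    haplotypes) in both pools; nan when the between-pool heterozygosity sums
    to zero.  Negative estimates are kept (not truncated)."""
    cw = allele_counts(wild.haplotypes).astype(float)
    cc = allele_counts(crop.haplotypes).astype(float)
    nw = cw.sum(axis=0)
    ncp = cc.sum(axis=0)
    ok = (nw >= 2) & (ncp >= 2)
    if not ok.any():
        return float("nan")
    pw = cw[:, ok] / nw[ok]
    pc = cc[:, ok] / ncp[ok]
    hw = 0.5 * (
        (nw[ok] / (nw[ok] - 1.0)) * (1.0 - (pw**2).sum(axis=0))
        + (ncp[ok] / (ncp[ok] - 1.0)) * (1.0 - (pc**2).sum(axis=0))
    )
    hb = 1.0 - (pw * pc).sum(axis=0)
    if hb.sum() <= 0:
        return float("nan")
    return float(1.0 - hw.sum() / hb.sum())


def diversity_ratio_and_class(
    pi_crop: float, pi_wild: float, baseline: float = 0.65
) -> tuple[float, str]:
    """Diversity ratio r = pi_crop/pi_wild and its selection class.

    Conventions: 0/0 and pi_wild = 0 -> undefined (r = nan or +inf); r = 0
    with polymorphic wild -> sweep_candidate; 0 < r < baseline -> reduced;
    baseline <= r <= 1 -> baseline; r > 1 -> elevated.
    """
    if not (np.isfinite(pi_wild) and np.isfinite(pi_crop)):
        return float("nan"), UNDEFINED
    if pi_wild == 0:
        return (float("nan"), UNDEFINED) if pi_crop == 0 else (float("inf"), UNDEFINED)
    r = pi_crop / pi_wild
    if r == 0:
        return r, SWEEP_CANDIDATE
    if r < baseline:
        return r, REDUCED
    if r <= 1:
        return r, BASELINE
    return r, ELEVATED


def genotype_matrix(pairs: list[tuple[GenePool, GenePool]]) -> tuple[np.ndarray, list[str]]:
    """Stack polymorphic sites of all genes into a (samples x loci) dosage
    matrix (count of the non-majority allele, nan for missing genotypes)."""
    cols = []
    names = None
    for wild, crop in pairs:
        names = wild.accessions + crop.accessions
        h = np.vstack([wild.haplotypes, crop.haplotypes])
        nind = h.shape[0] // 2
        counts = allele_counts(h)
        poly = (counts > 0).sum(axis=0) >= 2
        if not poly.any():
            continue
        hp = h[:, poly].reshape(nind, 2, -1).astype(float)
        major = counts[:, poly].argmax(axis=0)
        dose = (hp != major).sum(axis=1).astype(float)
        miss = (h[:, poly].reshape(nind, 2, -1) >= MISSING).any(axis=1)
        dose[miss] = np.nan
        cols.append(dose)
    if not cols:
        raise ValueError("no polymorphic sites in input")
    return np.hstack(cols), names


def genotype_pca(
    matrix: np.ndarray, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of a samples x loci matrix with mean imputation of
    missing entries and a deterministic sign convention (the largest-|loading|
    element of each component is made positive).  Returns (coordinates,
    explained variance ratios)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    from sklearn.decomposition import PCA

    k = min(n_components, min(X.shape) - 1) or 1
    p = PCA(n_components=k, svd_solver="full")
    coords = p.fit_transform(X)
    for j in range(coords.shape[1]):
        load = p.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    return coords, p.explained_variance_ratio_


def pool_stats(gene: GenePool) -> dict:
    """All within-pool statistics of one gene as a flat record."""
    sp, _ = site_pi(gene.haplotypes)
    used = ~np.isnan(sp)
    counts = allele_counts(gene.haplotypes)
    seg = ((counts > 0).sum(axis=0) >= 2) & used
    pis, pin, ratio = pi_syn_nonsyn(gene)
    f, _ = fixation_index(gene)
    return {
        "gene_id": gene.gene_id,
        "pool": gene.pool,
        "pi": float(np.nanmean(sp)) if used.any() else float("nan"),
        "pi_s": pis,
        "pi_n": pin,
        "pin_pis": ratio,
        "S": int(seg.sum()),
        "tajimas_d": tajimas_d(gene),
        "f_inbreeding": f,
        "n_sites_used": int(used.sum()),
    }


def pair_stats(wild: GenePool, crop: GenePool, baseline: float = 0.65) -> dict:
    """Between-pool statistics of one gene (F_ST, diversity ratio, class)."""
    pw = pi(wild)
    pc = pi(crop)
    r, cls = diversity_ratio_and_class(pc, pw, baseline=baseline)
    return {
        "gene_id": wild.gene_id,
        "fst": fst(wild, crop),
        "pi_wild": pw,
        "pi_crop": pc,
        "ratio": r,
        "selection_class": cls,
    }
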