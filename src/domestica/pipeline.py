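"""End-to-end orchestration: simulate (or load) -> popgen -> expression ->
comparative selection -> co-expression network -> joined report.

Every stage writes its table under the output directory; ``summary.json``
collects the headline numbers (diversity table, DE counts and direction
bias, CV-loss scans, regression table, KS contrasts, enrichments, module
table) together with the resolved configuration, so a run is fully
reproducible from its output directory alone.  Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import SimulationParams, simulate_genotypes, simulate_counts, write_fixtures, read_gene_fasta
from . import popgen, selection, network
from .expression import (
    exact_test_de, expression_cv, expression_pca, filter_expressed, tmm_factors,
)
from .popgen import CROP, WILD, GenePool

log = logging.getLogger("domestica")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (all thresholds surfaced)."""

    outdir: str = "results/run"
    seed: int = 0
    params: SimulationParams = field(default_factory=SimulationParams)
    fixtures_dir: str | None = None  # read fixtures instead of simulating
    min_called_per_pool: int = 5
    min_cpm: float = 1.0
    min_accessions: int = 5
    fdr: float = 0.01
    baseline_ratio: float = 0.65
    fst_percentiles: tuple[float, ...] = (90.0, 95.0, 99.0)
    n_resamples: int = 1000
    power: int = 20
    auto_power: bool = False
    merge_height: float = 0.25
    min_module_size: int = 30
    write_fixture_files: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.params, dict):
            self.params = SimulationParams(**self.params)
        self.params = dataclasses.replace(self.params, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def popgen_tables(
    pairs: list[tuple[GenePool, GenePool]],
    min_called_per_pool: int = 5,
    baseline_ratio: float = 0.65,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter sites and compute per-(gene x pool) statistics and per-gene
    pairwise comparisons for a list of (wild, crop) alignments."""
    pool_rows, pair_rows = [], []
    for wild, crop in pairs:
        w, c, info = popgen.filter_sites(wild, crop, min_called_per_pool)
        if info["empty"]:
            pair_rows.append({"gene_id": wild.gene_id, "fst": np.nan, "pi_wild": np.nan,
                              "pi_crop": np.nan, "ratio": np.nan,
                              "selection_class": popgen.UNDEFINED})
            continue
        pool_rows.append(popgen.pool_stats(w))
        pool_rows.append(popgen.pool_stats(c))
        pair_rows.append(popgen.pair_stats(w, c, baseline=baseline_ratio))
    return pd.DataFrame(pool_rows), pd.DataFrame(pair_rows)


def load_fixture_pairs(fixtures_dir: str | Path) -> list[tuple[GenePool, GenePool]]:
    """Read back every per-gene FASTA fixture under ``fixtures_dir``."""
    fdir = Path(fixtures_dir)
    labels = pd.read_csv(fdir / "labels.tsv", sep="\t", index_col=0)["pool"]
    wild_acc = list(labels.index[labels == WILD])
    crop_acc = list(labels.index[labels == CROP])
    return [read_gene_fasta(f, wild_acc, crop_acc)
            for f in sorted((fdir / "fasta").glob("*.fasta"))]


def validate_inputs(paths: dict[str, str | Path]) -> dict:
    """Machine-readable validation of user-supplied inputs.

    ``paths`` may contain ``fasta_dir``, ``counts``, ``labels``.  Returns
    {"errors": [...], "warnings": [...], "ok": bool}; errors are conditions
    under which the pipeline refuses to run.
    """
    errors: list[str] = []
    warnings: list[str] = []
    counts = labels = None
    if "counts" in paths:
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        if counts.index.duplicated().any():
            errors.append("duplicate gene ids in counts")
        vals = counts.to_numpy()
        if (vals < 0).any():
            errors.append("negative counts")
        if not np.allclose(vals, np.round(vals)):
            errors.append("non-integer counts")
    if "labels" in paths:
        labels = pd.read_csv(paths["labels"], sep="\t", index_col=0)["pool"]
        bad = set(labels.unique()) - {WILD, CROP}
        if bad:
            errors.append(f"unknown pool labels: {sorted(bad)}")
    if counts is not None and labels is not None:
        unlabeled = set(counts.columns) - set(labels.index)
        if unlabeled:
            errors.append(f"accessions in counts but not labels: {sorted(unlabeled)}")
    if "fasta_dir" in paths:
        from Bio import SeqIO

        for f in sorted(Path(paths["fasta_dir"]).glob("*.fasta")):
            lengths = {len(rec.seq) for rec in SeqIO.parse(str(f), "fasta")}
            if len(lengths) > 1:
                errors.append(f"{f.name}: unequal sequence lengths")
            elif lengths and next(iter(lengths)) % 3 != 0:
                errors.append(f"{f.name}: length not a multiple of 3")
    return {"errors": errors, "warnings": warnings, "ok": not errors}


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            t0 = time.perf_counter()
            out = fn(*a, **kw)
            log.info("stage %-12s %6.1fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the joined per-gene table plus summaries.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {"config": config.to_dict()}

    # ---- data ----------------------------------------------------------
    if config.fixtures_dir:
        pairs = load_fixture_pairs(config.fixtures_dir)
        fdir = Path(config.fixtures_dir)
        counts = pd.read_csv(fdir / "counts.tsv", sep="\t", index_col=0)
        labels = pd.read_csv(fdir / "labels.tsv", sep="\t", index_col=0)["pool"]
        ledger = pd.read_csv(fdir / "truth.tsv", sep="\t") if (fdir / "truth.tsv").exists() else None
    else:
        pairs, ledger = _stage("simulate")(simulate_genotypes)(config.params, rng)
        counts, labels, ledger = simulate_counts(config.params, ledger, rng)
        if config.write_fixture_files:
            write_fixtures(out / "fixtures", pairs, ledger, counts, labels, config.params)

    # ---- popgen --------------------------------------------------------
    pool_stats, pair_stats = _stage("popgen")(popgen_tables)(
        pairs, config.min_called_per_pool, config.baseline_ratio)
    pool_stats.to_csv(out / "popgen_pool_stats.tsv", sep="\t", index=False)
    wide = pool_stats.pivot(index="gene_id", columns="pool")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    # per-pool pi already lives in pair_stats as pi_wild / pi_crop
    wide = wide.drop(columns=["pi_wild", "pi_crop"], errors="ignore")
    master = pair_stats.set_index("gene_id").join(wide)

    fw, ci_w = popgen.fixation_index([w for w, _ in pairs], n_bootstrap=200, rng=rng)
    fc, ci_c = popgen.fixation_index([c for _, c in pairs], n_bootstrap=200, rng=rng)
    gm, names = popgen.genotype_matrix(pairs)
    g_coords, g_var = popgen.genotype_pca(gm)
    pd.DataFrame(g_coords[:, :5], index=names,
                 columns=[f"PC{i+1}" for i in range(g_coords[:, :5].shape[1])]) \
        .to_csv(out / "genotype_pca.tsv", sep="\t")

    finite_ratio = master["ratio"].replace([np.inf, -np.inf], np.nan).dropna()
    summary["diversity"] = {
        "n_genes": len(master),
        "mean_pi_wild_x1e3": 1e3 * master["pi_wild"].mean(),
        "mean_pi_crop_x1e3": 1e3 * master["pi_crop"].mean(),
        "mean_pis_wild_x1e3": 1e3 * wide.get("pi_s_wild", pd.Series(dtype=float)).mean(),
        "mean_pin_wild_x1e3": 1e3 * wide.get("pi_n_wild", pd.Series(dtype=float)).mean(),
        "median_tajimas_d_wild": wide.get("tajimas_d_wild", pd.Series(dtype=float)).median(),
        "median_tajimas_d_crop": wide.get("tajimas_d_crop", pd.Series(dtype=float)).median(),
        "f_wild": fw, "f_wild_ci": ci_w, "f_crop": fc, "f_crop_ci": ci_c,
        "mean_ratio": finite_ratio.mean(),
        "frac_ratio_zero": float((master["ratio"] == 0).mean()),
        "frac_ratio_gt1": float((finite_ratio > 1).mean()),
        "mean_fst": master["fst"].mean(),
        "genotype_pc1_varexp": float(g_var[0]),
        "class_counts": master["selection_class"].value_counts().to_dict(),
    }

    # ---- expression ----------------------------------------------------
    t0 = time.perf_counter()
    kept = filter_expressed(counts, labels, config.min_accessions, config.min_cpm)
    tmm = tmm_factors(kept)
    de = exact_test_de(kept, labels, fdr=config.fdr)
    cv = expression_cv(kept, labels, tmm=tmm)
    e_coords, e_var = expression_pca(kept, tmm=tmm)
    e_coords.to_csv(out / "expression_pca.tsv", sep="\t")
    expr_results = de.join(cv)
    expr_results.to_csv(out / "expression_results.tsv", sep="\t")
    log.info("stage %-12s %6.1fs", "expression", time.perf_counter() - t0)

    master = master.join(expr_results, how="left")
    bias = selection.direction_bias_test(de["de"], de["logfc"])
    summary["expression"] = {
        "n_genes_raw": len(counts), "n_genes_filtered": len(kept),
        "n_de": int(de["de"].sum()), "fdr": config.fdr,
        "frac_down_in_crop_de": bias["frac_down_de"],
        "frac_down_in_crop_all": bias["frac_down_all"],
        "direction_bias_p": bias["p"],
        "mean_cv_wild": cv["cv_wild"].mean(), "mean_cv_crop": cv["cv_crop"].mean(),
        "cv_ratio": cv["cv_crop"].mean() / cv["cv_wild"].mean(),
        "expression_pc1_varexp": float(e_var[0]),
    }

    # ---- comparative selection ----------------------------------------
    t0 = time.perf_counter()
    scans = {}
    for pct in config.fst_percentiles:
        scan = selection.matched_resampling_test(
            master["cv_wild"], master["cv_crop"], master["pi_wild"], master["fst"],
            percentile=pct, n_resamples=config.n_resamples,
            rng=np.random.default_rng(config.seed + int(pct)),
        )
        scans[str(int(pct))] = {
            "cutoff": scan.cutoff, "n_outliers": len(scan.outlier_genes),
            "observed_delta_cv": scan.observed_delta_cv,
            "cv_loss_percent": 100.0 * scan.cv_loss_fraction,
            "p": scan.p_value, "n_relaxed": scan.n_relaxed,
        }
    summary["cv_loss_scans"] = scans

    de_flags = master["de"].fillna(False).astype(bool)
    summ_tab, ks_tab = selection.de_vs_nonde_distributions(master, de_flags)
    summ_tab.to_csv(out / "de_vs_nonde_summaries.tsv", sep="\t", index=False)
    summary["de_vs_nonde_ks"] = ks_tab.set_index("statistic")["ks_p"].to_dict()

    low_ratio = (master["ratio"] < 0.1) & master["ratio"].notna()
    fst95 = master["fst"] >= np.nanpercentile(master["fst"], 95)
    summary["enrichment"] = {
        "de_low_ratio": selection.enrichment_2x2(de_flags, low_ratio) | {},
        "de_high_fst": selection.enrichment_2x2(de_flags, fst95) | {},
    }
    for v in summary["enrichment"].values():
        v.pop("table", None)

    regs = {}
    for stat_col in ("pi_s", "pi_n", "pin_pis"):
        both = pd.concat([
            pd.DataFrame({"stat": wide.get(f"{stat_col}_{pool}"),
                          "expr": master[f"mean_cpm_{pool}"],
                          "pool": pool})
            for pool in (WILD, CROP)
        ])
        try:
            regs[stat_col] = selection.polymorphism_expression_regression(
                both["stat"], both["expr"], both["pool"])
        except ValueError:
            regs[stat_col] = None
    summary["regressions"] = regs

    zero_fst = selection.zero_fst_candidates(de_flags, master["fst"])
    zero_fst.to_csv(out / "regulatory_only_candidates.tsv", sep="\t", index=False)
    summary["n_zero_fst_de"] = len(zero_fst)
    log.info("stage %-12s %6.1fs", "selection", time.perf_counter() - t0)

    # ---- network -------------------------------------------------------
    t0 = time.perf_counter()
    expr = network.log_cpm(kept, tmm).to_numpy()
    if config.auto_power:
        beta, _fits = network.pick_soft_power(expr)
    else:
        beta = config.power
    diss = network.build_tom(expr, beta=beta)
    modules = network.detect_modules(
        diss, expr, beta=beta, min_module_size=config.min_module_size,
        merge_height=config.merge_height, sample_names=list(kept.columns))
    pools_arr = labels.reindex(kept.columns).to_numpy()
    enr = network.module_enrichment(modules, de_flags.reindex(kept.index).fillna(False),
                                    expr=expr, pools=pools_arr)
    enr.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
    if len(modules.eigengenes):
        modules.eigengenes.to_csv(out / "module_eigengenes.tsv", sep="\t")
        network.outlier_accession_report(modules, labels) \
            .to_csv(out / "module_accession_report.tsv", sep="\t", index=False)
    master["module"] = pd.Series(modules.labels, index=kept.index).reindex(master.index)
    summary["network"] = {
        "beta": beta, "n_modules": modules.n_modules, "sizes": modules.sizes,
        "n_enriched_fdr05": int((enr["q"] <= 0.05).sum()) if len(enr) else 0,
    }
    log.info("stage %-12s %6.1fs", "network", time.perf_counter() - t0)

    # ---- outputs -------------------------------------------------------
    if ledger is not None:
        master = master.join(ledger.set_index("gene_id"), how="left")
    master.to_csv(out / "master_genes.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
    return summary
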