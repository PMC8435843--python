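"""Joint polymorphism-expression comparisons.

Joins the popgen and expression tables, runs the diversity-matched
resampling test for CV loss in F_ST outliers (90/95/99th percentiles), the
DE vs non-DE distribution and enrichment comparisons, the down-regulation
bias test, the log-log polymorphism~expression regressions, and the
F_ST = 0 regulatory-only candidate scan.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from domestica import selection  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    pair = pd.read_csv(BASE / "popgen_pair_stats.tsv", sep="\t", index_col=0)
    pool = pd.read_csv(BASE / "popgen_pool_stats.tsv", sep="\t")
    expr = pd.read_csv(BASE / "expression_results.tsv", sep="\t", index_col=0)
    wide = pool.pivot(index="gene_id", columns="pool")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    master = pair.join(wide.drop(columns=["pi_wild", "pi_crop"], errors="ignore")).join(expr)
    master.to_csv(BASE / "master_genes.tsv", sep="\t")

    out: dict = {"cv_loss_scans": {}}
    print("diversity-matched CV-loss scans (F_ST outliers):")
    for pct in (90, 95, 99):
        scan = selection.matched_resampling_test(
            master["cv_wild"], master["cv_crop"], master["pi_wild"], master["fst"],
            percentile=pct, n_resamples=1000, rng=np.random.default_rng(SEED + pct))
        out["cv_loss_scans"][str(pct)] = {
            "cv_loss_percent": 100 * scan.cv_loss_fraction, "p": scan.p_value,
            "n_outliers": len(scan.outlier_genes)}
        print(f"  {pct}th pct: {len(scan.outlier_genes):4d} outliers, "
              f"CV loss {100 * scan.cv_loss_fraction:5.1f}%, p = {scan.p_value:.3f}")

    de = master["de"].fillna(False).astype(bool)
    summaries, ks = selection.de_vs_nonde_distributions(master, de)
    summaries.to_csv(BASE / "de_vs_nonde_summaries.tsv", sep="\t", index=False)
    out["ks_tests"] = ks.set_index("statistic")["ks_p"].to_dict()
    bias = selection.direction_bias_test(de, master["logfc"])
    out["direction_bias"] = bias

    low_ratio = master["ratio"].lt(0.1) & master["ratio"].notna()
    high_fst = master["fst"] >= np.nanpercentile(master["fst"], 95)
    out["enrichment_de_low_ratio"] = {
        k: v for k, v in selection.enrichment_2x2(de, low_ratio).items() if k != "table"}
    out["enrichment_de_high_fst"] = {
        k: v for k, v in selection.enrichment_2x2(de, high_fst).items() if k != "table"}
    print(f"DE enrichment: ratio<0.1 p={out['enrichment_de_low_ratio']['p']:.3f}, "
          f"F_ST top-5% p={out['enrichment_de_high_fst']['p']:.3f}")

    regs = {}
    for stat_col in ("pi_s", "pi_n", "pin_pis"):
        both = pd.concat([
            pd.DataFrame({"stat": wide[f"{stat_col}_{p_}"],
                          "expr": master[f"mean_cpm_{p_}"], "pool": p_})
            for p_ in ("wild", "crop")])
        regs[stat_col] = selection.polymorphism_expression_regression(
            both["stat"], both["expr"], both["pool"])
        per = regs[stat_col]["per_pool"]
        print(f"log-log regression {stat_col}: " + "; ".join(
            f"{p_} slope={v['slope']:+.2f} (adjR2={v['adj_r2']:.2f})" for p_, v in per.items())
            + f"; interaction p={regs[stat_col]['interaction']['p']:.2f}")
    out["regressions"] = regs

    zf = selection.zero_fst_candidates(de, master["fst"])
    zf.to_csv(BASE / "regulatory_only_candidates.tsv", sep="\t", index=False)
    out["n_zero_fst_de"] = len(zf)
    print(f"{len(zf)} DE genes with F_ST <= 0 (regulatory-only candidates)")

    with open(BASE / "selection_tests.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True, default=float)


if __name__ == "__main__":
    main()
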