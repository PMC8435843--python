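"""Signed co-expression network modules and their DE enrichment.

Builds the signed TOM at power 20, detects and merges modules, tests each
module for enrichment in DE genes, and screens accessions for outlying
module eigengene scores.  Compares detected modules against the planted
ground truth from step 01.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from domestica import network  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts = pd.read_csv(BASE / "data" / "counts.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(BASE / "data" / "labels.tsv", sep="\t", index_col=0)["pool"]
    truth = pd.read_csv(BASE / "data" / "truth.tsv", sep="\t", index_col=0)
    master = pd.read_csv(BASE / "master_genes.tsv", sep="\t", index_col=0)

    expr = network.log_cpm(counts).to_numpy()
    diss = network.build_tom(expr, beta=20)
    ms = network.detect_modules(diss, expr, beta=20, sample_names=list(counts.columns))
    print(f"beta=20: {ms.n_modules} modules, sizes {ms.sizes}")

    de = master["de"].reindex(counts.index).fillna(False).astype(bool)
    enr = network.module_enrichment(ms, de, expr=expr,
                                    pools=labels.reindex(counts.columns).to_numpy())
    enr.to_csv(BASE / "module_enrichment.tsv", sep="\t", index=False)
    for _, row in enr.iterrows():
        print(f"  module {int(row['module'])} (n={int(row['size'])}, "
              f"{row['direction_crop']} in crop): {int(row['n_flagged'])} DE genes, "
              f"OR={row['odds_ratio']:.1f}, q={row['q']:.3f}")

    mask = truth["module_id"].to_numpy() > 0
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(truth["module_id"].to_numpy()[mask], ms.labels[mask])
    print(f"planted-module recovery: ARI = {ari:.2f} over {mask.sum()} planted genes")

    ms.eigengenes.to_csv(BASE / "module_eigengenes.tsv", sep="\t")
    report = network.outlier_accession_report(ms, labels)
    report.to_csv(BASE / "module_accession_report.tsv", sep="\t", index=False)
    flagged = report[report["flagged"]]
    if len(flagged):
        print("outlying accessions (|z| > 2.5):",
              ", ".join(f"{r.accession} in {r.module}" for r in flagged.itertuples()))
    else:
        print("no accession exceeds |z| > 2.5 in any module eigengene")


if __name__ == "__main__":
    main()
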