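"""Per-gene coding-sequence diversity and differentiation.

Reads the fixtures from step 01, applies the >= 5-called-individuals site
filter, and computes pi, piS, piN, piN/piS, Tajima's D and F within pools,
plus Hudson F_ST and the pi_crop/pi_wild selection classification between
pools.  Writes the per-gene tables and prints a diversity summary in the
style of a wild-vs-domesticate comparison table.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from domestica import popgen  # noqa: E402
from domestica.pipeline import load_fixture_pairs, popgen_tables  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pairs = load_fixture_pairs(BASE / "data")
    pool_stats, pair_stats = popgen_tables(pairs)
    pool_stats.to_csv(BASE / "popgen_pool_stats.tsv", sep="\t", index=False)
    pair_stats.to_csv(BASE / "popgen_pair_stats.tsv", sep="\t", index=False)

    fw, ci_w = popgen.fixation_index([w for w, _ in pairs], n_bootstrap=200,
                                     rng=np.random.default_rng(1))
    fc, ci_c = popgen.fixation_index([c for _, c in pairs], n_bootstrap=200,
                                     rng=np.random.default_rng(2))
    print("pool summaries (pi values x 1e3):")
    for pool, f, ci in (("wild", fw, ci_w), ("crop", fc, ci_c)):
        sub = pool_stats[pool_stats["pool"] == pool]
        print(f"  {pool:5s} mean pi={1e3 * sub.pi.mean():.2f}  piS={1e3 * sub.pi_s.mean():.2f}  "
              f"piN={1e3 * sub.pi_n.mean():.2f}  piN/piS={sub.pi_n.mean() / sub.pi_s.mean():.2f}  "
              f"median D={sub.tajimas_d.median():+.2f}  F={f:.2f} [{ci[0]:.2f}; {ci[1]:.2f}]")
    r = pair_stats["ratio"].replace([np.inf], np.nan).dropna()
    print(f"mean pi_crop/pi_wild = {r.mean():.2f}; "
          f"{(pair_stats.ratio == 0).mean():.0%} of genes at ratio 0, "
          f"{(r > 1).mean():.0%} above 1; mean F_ST = {pair_stats.fst.mean():.2f}")

    gm, names = popgen.genotype_matrix(pairs)
    coords, var = popgen.genotype_pca(gm)
    pd.DataFrame(coords[:, :5], index=names,
                 columns=[f"PC{i+1}" for i in range(5)]).to_csv(
        BASE / "genotype_pca.tsv", sep="\t")
    wild = [n.startswith("W") for n in names]
    sep = (coords[wild, 0].max() < coords[[not w for w in wild], 0].min()
           or coords[wild, 0].min() > coords[[not w for w in wild], 0].max())
    print(f"genotype PCA: PC1 explains {100 * var[0]:.1f}% and "
          f"{'separates' if sep else 'does not separate'} the pools")


if __name__ == "__main__":
    main()
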