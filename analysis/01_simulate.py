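"""Generate the synthetic wild/domesticated dataset used by all downstream
analysis steps.

Writes per-gene FASTA haplotype alignments, a VCF-like site table, the raw
count matrix, pool labels and the ground-truth ledger under
results/data/, and prints a short description of the stated world.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from domestica.simulate import (  # noqa: E402
    SimulationParams, simulate_genotypes, simulate_counts, write_fixtures,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    params = SimulationParams(n_genes=2000, seed=SEED)
    rng = np.random.default_rng(SEED)
    pairs, ledger = simulate_genotypes(params, rng)
    counts, labels, ledger = simulate_counts(params, ledger, rng)
    write_fixtures(OUT, pairs, ledger, counts, labels, params)
    print(f"simulated {params.n_genes} genes x {params.n_wild}+{params.n_crop} accessions")
    print(f"  swept genes: {int(ledger.is_swept.sum())}, DE genes: {int(ledger.is_de.sum())} "
          f"({ledger.loc[ledger.is_de, 'true_lfc'].gt(0).mean():.0%} down in crop), "
          f"modules: {ledger.module_id.max()} x {params.module_size}")
    print(f"  wrote fixtures to {OUT}")


if __name__ == "__main__":
    main()
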