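import numpy as np
import pytest

from domestica.popgen import CROP, WILD, GenePool
from domestica.simulate import SimulationParams, simulate_counts, simulate_genotypes


def make_pool(seqs: list[str], pool: str = WILD, gene_id: str = "g1") -> GenePool:
    """Build a GenePool from haplotype strings (2 per accession, 'N' = missing)."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    hap = np.array([[code[ch] for ch in s] for s in seqs], dtype=np.uint8)
    acc = [f"{pool[0].upper()}{i+1:02d}" for i in range(len(seqs) // 2)]
    return GenePool(gene_id, pool, acc, hap)


@pytest.fixture(scope="session")
def default_world():
    """One 2000-gene simulation at the default parameters (the stated world):
    genotypes, counts, labels and the truth ledger."""
    params = SimulationParams(n_genes=2000, seed=1)
    rng = np.random.default_rng(1)
    pairs, ledger = simulate_genotypes(params, rng)
    counts, labels, ledger = simulate_counts(params, ledger, rng)
    return {"params": params, "pairs": pairs, "ledger": ledger,
            "counts": counts, "labels": labels}


@pytest.fixture(scope="session")
def default_master(default_world):
    """Joined per-gene table (popgen + expression) for the default world."""
    import pandas as pd

    from domestica.expression import exact_test_de, expression_cv, tmm_factors
    from domestica.pipeline import popgen_tables

    pool_stats, pair_stats = popgen_tables(default_world["pairs"])
    counts, labels = default_world["counts"], default_world["labels"]
    tmm = tmm_factors(counts)
    de = exact_test_de(counts, labels)
    cv = expression_cv(counts, labels, tmm=tmm)
    master = pair_stats.set_index("gene_id").join(de).join(cv)
    master = master.join(default_world["ledger"].set_index("gene_id"), how="left")
    return {"master": master, "pool_stats": pool_stats}
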