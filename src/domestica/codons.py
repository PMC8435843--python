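"""Codon-level bookkeeping for synonymous/nonsynonymous diversity.

Precomputes, for the universal genetic code:

* per-codon synonymous and nonsynonymous site counts (Nei & Gojobori 1986
  mutation-fraction convention: the synonymous fraction of a position is the
  number of synonymous single-base changes divided by 3, so syn + nonsyn
  sites always sum to exactly 3 per codon);
* per-codon-pair synonymous/nonsynonymous difference counts, averaged over
  the shortest mutational pathways between the two codons, excluding
  pathways that pass through a stop codon (all-stop pathways fall back to
  the unrestricted average).

Codons are indexed 0..63 as 16*b1 + 4*b2 + b3 with A,C,G,T -> 0..3.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: integer code used for a missing/ambiguous base in haplotype matrices
MISSING = 4

_TABLE = unambiguous_dna_by_id[1]  # universal code


def codon_str(idx: int) -> str:
    return BASES[(idx >> 4) & 3] + BASES[(idx >> 2) & 3] + BASES[idx & 3]


def codon_index(codon: str) -> int:
    return (BASE_INDEX[codon[0]] << 4) | (BASE_INDEX[codon[1]] << 2) | BASE_INDEX[codon[2]]


AMINO = np.array(
    ["*" if codon_str(i) in _TABLE.stop_codons else _TABLE.forward_table[codon_str(i)]
     for i in range(64)]
)
IS_STOP = AMINO == "*"
STOP_INDICES = frozenset(int(i) for i in np.flatnonzero(IS_STOP))
NON_STOP_INDICES = np.flatnonzero(~IS_STOP)


def _neighbors(idx: int):
    """All 9 single-base mutants of a codon, as (position, new_index)."""
    for pos in range(3):
        shift = (2 - pos) * 2
        base = (idx >> shift) & 3
        for b in range(4):
            if b != base:
                yield pos, (idx & ~(3 << shift)) | (b << shift)


def _site_counts() -> tuple[np.ndarray, np.ndarray]:
    syn = np.full(64, np.nan)
    for idx in range(64):
        if IS_STOP[idx]:
            continue
        s = 0.0
        for _pos, j in _neighbors(idx):
            # mutations to stop codons count as nonsynonymous so that
            # syn + nonsyn sites sum to exactly 3
            if not IS_STOP[j] and AMINO[j] == AMINO[idx]:
                s += 1.0
        syn[idx] = s / 3.0
    return syn, 3.0 - syn


#: NG86 synonymous / nonsynonymous site counts per codon (nan for stops)
SYN_SITES, NONSYN_SITES = _site_counts()


def _mutate(idx: int, pos: int, base: int) -> int:
    shift = (2 - pos) * 2
    return (idx & ~(3 << shift)) | (base << shift)


def _path_diffs(c1: int, c2: int) -> tuple[float, float]:
    """Mean (syn, nonsyn) difference counts over mutational pathways c1->c2."""
    positions = [p for p in range(3) if ((c1 >> ((2 - p) * 2)) & 3) != ((c2 >> ((2 - p) * 2)) & 3)]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            shift = (2 - pos) * 2
            nxt = _mutate(cur, pos, (c2 >> shift) & 3)
            steps.append((cur, nxt))
            if IS_STOP[nxt] and nxt != c2:
                through_stop = True
            cur = nxt
        syn = sum(1.0 for a, b in steps if AMINO[a] == AMINO[b] and not IS_STOP[a] and not IS_STOP[b])
        non = len(steps) - syn
        paths.append((through_stop, syn, non))
    valid = [(s, n) for stop, s, n in paths if not stop]
    if not valid:  # every pathway crosses a stop: fall back to all pathways
        valid = [(s, n) for _stop, s, n in paths]
    syn = float(np.mean([v[0] for v in valid]))
    non = float(np.mean([v[1] for v in valid]))
    return syn, non


def _diff_tables() -> tuple[np.ndarray, np.ndarray]:
    syn = np.full((64, 64), np.nan)
    non = np.full((64, 64), np.nan)
    for c1 in NON_STOP_INDICES:
        for c2 in NON_STOP_INDICES:
            s, n = _path_diffs(int(c1), int(c2))
            syn[c1, c2] = s
            non[c1, c2] = n
    return syn, non


#: pathway-averaged pairwise difference counts (nan rows/cols for stops)
SYN_DIFFS, NONSYN_DIFFS = _diff_tables()


def _pos_alt_class() -> np.ndarray:
    """(64, 3, 4) class of changing codon position p to base b:
    -1 = no change, 0 = creates a stop, 1 = synonymous, 2 = nonsynonymous
    (stop codons themselves are all -1)."""
    cls = np.full((64, 3, 4), -1, dtype=np.int8)
    for idx in NON_STOP_INDICES:
        for pos in range(3):
            shift = (2 - pos) * 2
            cur = (idx >> shift) & 3
            for b in range(4):
                if b == cur:
                    continue
                mut = (int(idx) & ~(3 << shift)) | (b << shift)
                if IS_STOP[mut]:
                    cls[idx, pos, b] = 0
                elif AMINO[mut] == AMINO[idx]:
                    cls[idx, pos, b] = 1
                else:
                    cls[idx, pos, b] = 2
    return cls


#: mutation-class lookup used by the synthetic-data generator
POS_ALT_CLASS = _pos_alt_class()


def encode_codons(haplotypes: np.ndarray) -> np.ndarray:
    """Map a (n_hap, L) base-code matrix to a (n_hap, L//3) codon-index matrix.

    Codons containing a missing base, or that are stop codons, are coded -1
    (skipped in pairwise comparisons).
    """
    n, L = haplotypes.shape
    ncod = L // 3
    h = haplotypes[:, : ncod * 3].reshape(n, ncod, 3)
    bad = (h >= MISSING).any(axis=2)
    hc = np.where(h >= MISSING, 0, h).astype(np.int16)
    idx = (hc[:, :, 0] << 4) | (hc[:, :, 1] << 2) | hc[:, :, 2]
    idx[bad] = -1
    idx[IS_STOP[np.clip(idx, 0, 63)] & (idx >= 0)] = -1
    return idx
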