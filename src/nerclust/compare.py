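"""Rand Index and Adjusted Rand Index between two partitions.

Both indices count, over every unordered pair of sites, whether the pair
is grouped the same way by two partitions. The raw Rand Index is the
proportion of concordant pairs (together in both, or apart in both); it is
1 for identical partitions but its expectation under random labelling
floats with the group sizes. The Adjusted Rand Index (Hubert & Arabie)
rescales it with the permutation-model expectation so that random
agreement scores 0 while perfect agreement stays 1:

    ARI = (sum_ij C(n_ij,2) - E) / (max - E),
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2),
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2,

with n_ij the contingency counts between the two partitions and a_i, b_j
its margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairContingency", "pair_contingency", "rand_index", "adjusted_rand_index"]


@dataclass(frozen=True)
class PairContingency:
    """Contingency counts n_ij between clusters of two partitions of the same sites."""

    table: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int


def _labels(p) -> np.ndarray:
    labels = np.asarray(getattr(p, "labels", p))
    if labels.ndim != 1:
        raise ValueError("a partition is a 1-D label vector")
    return labels


def pair_contingency(pa, pb) -> PairContingency:
    a, b = _labels(pa), _labels(pb)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same sites")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return PairContingency(
        table=table,
        row_sums=table.sum(axis=1),
        col_sums=table.sum(axis=0),
        n=a.size,
    )


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def rand_index(pa, pb) -> float:
    """Proportion of site pairs grouped concordantly by both partitions, in [0, 1]."""
    ct = pair_contingency(pa, pb)
    if ct.n < 2:
        raise ValueError("need at least two sites to compare pairs")
    total = _comb2(np.array(ct.n)).item()
    both = _comb2(ct.table).sum()  # together in both
    same_a = _comb2(ct.row_sums).sum()
    same_b = _comb2(ct.col_sums).sum()
    disagreements = same_a + same_b - 2.0 * both
    return float(1.0 - disagreements / total)


def adjusted_rand_index(pa, pb) -> float:
    """Chance-corrected Rand Index: 0 expected under random labelling, 1 iff equal.

    Degenerate cases where the adjustment denominator vanishes (both
    partitions all-singletons, or both one single cluster) are defined as
    1 when the partitions agree up to relabelling and 0 otherwise, the
    dominant convention in the literature.
    """
    ct = pair_contingency(pa, pb)
    if ct.n < 2:
        raise ValueError("need at least two sites to compare pairs")
    total = _comb2(np.array(ct.n)).item()
    index = _comb2(ct.table).sum()
    same_a = _comb2(ct.row_sums).sum()
    same_b = _comb2(ct.col_sums).sum()
    expected = same_a * same_b / total
    max_index = 0.5 * (same_a + same_b)
    if max_index == expected:
        nz = ct.table > 0
        identical = bool((nz.sum(axis=0) == 1).all() and (nz.sum(axis=1) == 1).all())
        return 1.0 if identical else 0.0
    return float((index - expected) / (max_index - expected))
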