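"""Clustering-agreement statistics: entropy, MI, NMI, RI and ARI.

All quantities are computed from first principles on the contingency table
of the two partitions (natural logarithms throughout; NMI is base-invariant
because numerator and denominator share the base). These are deliberately
not delegated to a library implementation.

Conventions for degenerate inputs:
- NMI when both partitions are single-cluster (H1 + H2 = 0): 1 if the
  partitions are identical up to relabeling, else 0.
- ARI when max(RI) equals E(RI) (both partitions trivial — all singletons
  or all one cluster): 1 if the contingency tables agree up to relabeling,
  else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation n_ij of two partitions of the same m items."""

    counts: np.ndarray

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PairCounts:
    """Unordered-pair concordance counts between two partitions.

    a: together in both; b: apart in both; c: together in the first only;
    d: together in the second only. a + b + c + d = m(m-1)/2.
    """

    a: int
    b: int
    c: int
    d: int


def _as_codes(p: Sequence) -> np.ndarray:
    arr = np.asarray(list(p), dtype=object)
    _, codes = np.unique(arr.astype(str), return_inverse=True)
    return codes


def contingency(p1: Sequence, p2: Sequence) -> ContingencyTable:
    """n_ij = number of items in cluster i of p1 and cluster j of p2."""
    c1, c2 = _as_codes(p1), _as_codes(p2)
    if len(c1) != len(c2):
        raise ValueError(f"partition lengths differ: {len(c1)} vs {len(c2)}")
    r, c = c1.max() + 1, c2.max() + 1
    counts = np.zeros((r, c), dtype=int)
    np.add.at(counts, (c1, c2), 1)
    return ContingencyTable(counts)


def entropy(p: Sequence) -> float:
    """Shannon entropy of cluster sizes in nats; 0 ln 0 := 0."""
    codes = _as_codes(p)
    m = len(codes)
    if m < 1:
        raise ValueError("partition must be non-empty")
    sizes = np.bincount(codes)
    probs = sizes[sizes > 0] / m
    return float(-np.sum(probs * np.log(probs)))


def mutual_information(p1: Sequence, p2: Sequence) -> float:
    """I(p1; p2) in nats from the joint cell frequencies; zero cells add 0."""
    table = contingency(p1, p2).counts
    m = table.sum()
    joint = table / m
    pi = table.sum(axis=1) / m
    pj = table.sum(axis=0) / m
    outer = np.outer(pi, pj)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def nmi(p1: Sequence, p2: Sequence) -> float:
    """Normalized mutual information 2 I / (H1 + H2) in [0, 1]."""
    h1, h2 = entropy(p1), entropy(p2)
    if h1 + h2 == 0.0:
        return 1.0 if _same_partition(p1, p2) else 0.0
    value = 2.0 * mutual_information(p1, p2) / (h1 + h2)
    return float(min(max(value, 0.0), 1.0))


def _same_partition(p1: Sequence, p2: Sequence) -> bool:
    table = contingency(p1, p2).counts
    return (np.count_nonzero(table, axis=1) <= 1).all() and (
        np.count_nonzero(table, axis=0) <= 1
    ).all()


def _comb2(x: np.ndarray | int) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def pair_counts(p1: Sequence, p2: Sequence) -> PairCounts:
    """Concordance counts over all m(m-1)/2 unordered pairs.

    Computed via contingency identities; equal to exhaustive enumeration.
    """
    table = contingency(p1, p2)
    m = table.total
    if m < 2:
        raise ValueError("pair counts need at least 2 items")
    total_pairs = _comb2(m)
    a = float(np.sum(_comb2(table.counts)))
    same1 = float(np.sum(_comb2(table.row_sums)))
    same2 = float(np.sum(_comb2(table.col_sums)))
    c = same1 - a
    d = same2 - a
    b = total_pairs - a - c - d
    return PairCounts(int(a), int(b), int(c), int(d))


def rand_index(p1: Sequence, p2: Sequence) -> float:
    """(a + b) / C(m, 2): fraction of concordant pairs."""
    pc = pair_counts(p1, p2)
    return (pc.a + pc.b) / (pc.a + pc.b + pc.c + pc.d)


def adjusted_rand_index(p1: Sequence, p2: Sequence) -> float:
    """Chance-corrected RI: (Index - E) / (Max - E) on C(n_ij, 2) sums."""
    table = contingency(p1, p2)
    m = table.total
    if m < 2:
        raise ValueError("ARI needs at least 2 items")
    index = float(np.sum(_comb2(table.counts)))
    sum_rows = float(np.sum(_comb2(table.row_sums)))
    sum_cols = float(np.sum(_comb2(table.col_sums)))
    expected = sum_rows * sum_cols / _comb2(m)
    maximum = 0.5 * (sum_rows + sum_cols)
    if maximum == expected:
        return 1.0 if _same_partition(p1, p2) else 0.0
    return (index - expected) / (maximum - expected)
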