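"""Permutation-contrast construction: negative pseudo-cells and the training set.

Each gene column of the real matrix X is shuffled independently to form Z.
The shuffle preserves every per-gene marginal distribution exactly while
destroying the gene-gene dependence carried by cell identity, so a
classifier that separates rows of X from rows of Z must exploit inter-gene
structure — exactly the structure cluster-informative genes carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix


@dataclass(frozen=True)
class TrainingSet:
    """Stacked real and permuted cells with binary class labels.

    ``features`` is the 2m x n vertical stack [X; Z]; ``labels`` is 1 for
    the first m rows (real cells) and 0 for the last m (permuted cells).
    """

    features: np.ndarray
    labels: np.ndarray
    gene_ids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.labels):
            raise ValueError("features and labels misaligned")
        if self.features.shape[0] % 2 != 0:
            raise ValueError("training set must have an even number of rows")

    @property
    def n_cells(self) -> int:
        return self.features.shape[0] // 2

    @property
    def n_genes(self) -> int:
        return self.features.shape[1]


def permute_columns(
    x: ExpressionMatrix, seed: int, shared: bool = False
) -> np.ndarray:
    """Return Z: every gene column shuffled across cells.

    Columns get mutually independent permutations derived from ``seed`` via
    spawned RNG streams (so the result is reproducible for a fixed seed but
    not stable under column reordering). With ``shared=True`` a single
    permutation is applied to all columns — this preserves inter-gene
    structure and exists only for comparison experiments.
    """
    m = x.n_cells
    if m < 2:
        raise ValueError(f"need at least 2 cells to permute, got {m}")
    root = np.random.default_rng(seed)
    if shared:
        perm = root.permutation(m)
        return x.values[perm, :].copy()
    z = np.empty_like(x.values)
    streams = root.spawn(x.n_genes)
    for j, rng in enumerate(streams):
        z[:, j] = x.values[rng.permutation(m), j]
    return z


def build_training_set(
    x: ExpressionMatrix, seed: int, shared_permutation: bool = False
) -> TrainingSet:
    """Stack X on top of its column-permuted copy Z with labels [1]*m + [0]*m."""
    z = permute_columns(x, seed, shared=shared_permutation)
    features = np.vstack([x.values, z])
    labels = np.concatenate(
        [np.ones(x.n_cells, dtype=int), np.zeros(x.n_cells, dtype=int)]
    )
    return TrainingSet(features, labels, x.gene_ids, seed)
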