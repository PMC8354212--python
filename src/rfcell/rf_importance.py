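"""Random-forest real-vs-permuted classification and OOB permutation importance.

The forest is an explicit bagged ensemble of CART trees so that each tree's
bootstrap (in-bag) rows — and hence its out-of-bag (OOB) rows — are known.
Mean decrease accuracy (MDA) for gene j is the average, over trees, of the
drop in that tree's OOB accuracy when column j is shuffled within the OOB
rows. Genes with MDA strictly greater than zero are selected.

Defaults mirror classification defaults of classical random-forest
implementations: 500 trees, mtry = floor(sqrt(n_genes)) candidate features
per split, bootstrap with replacement of the full training-set size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .datamodel import ExpressionMatrix, GeneSet, sorted_gene_set
from .negative_sampling import TrainingSet, build_training_set

logger = logging.getLogger("rfcell")

_MAX_SEED = 2**31 - 1


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n reproducible 31-bit sub-seeds from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % _MAX_SEED


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    mtry and bootstrap_size default to ``None`` meaning floor(sqrt(n_genes))
    and the full row count (sampling with replacement), resolved at fit time.
    scale_mda divides each gene's raw MDA by its standard error over trees;
    the sign — all the selection rule uses — is unchanged wherever that
    standard error is nonzero.
    """

    n_trees: int = 500
    mtry: int | None = None
    bootstrap_size: int | None = None
    seed: int = 0
    scale_mda: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError(f"mtry must be >= 1, got {self.mtry}")


@dataclass
class ForestModel:
    """A fitted bagged ensemble with exposed per-tree bootstrap bookkeeping."""

    trees: list[DecisionTreeClassifier]
    inbag_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    mtry: int
    config: ForestConfig

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_vote_predictions(self, features: np.ndarray) -> np.ndarray:
        """Majority-vote class for each row over the trees holding it OOB.

        Rows never OOB get -1 (possible only for very small forests).
        """
        n = features.shape[0]
        votes = np.zeros((n, 2), dtype=int)
        x32 = np.ascontiguousarray(features, dtype=np.float32)
        for tree, oob in zip(self.trees, self.oob_indices):
            if oob.size == 0:
                continue
            pred = tree.predict(x32[oob], check_input=False).astype(int)
            votes[oob, pred] += 1
        out = np.where(votes.sum(axis=1) > 0, votes.argmax(axis=1), -1)
        return out


@dataclass(frozen=True)
class ImportanceReport:
    """Per-gene MDA plus forest/OOB diagnostics."""

    gene_ids: np.ndarray
    mda: np.ndarray
    per_tree_oob_accuracy: np.ndarray
    oob_accuracy: float
    n_trees_used: int
    config: ForestConfig
    scaled: bool = False


def fit_forest(ts: TrainingSet, cfg: ForestConfig) -> ForestModel:
    """Train ``cfg.n_trees`` CART trees on bootstrap resamples of ts.

    Each tree considers ``mtry`` candidate features per split and grows to
    purity (unit leaves), the classification default. Raises on degenerate
    single-class labels.
    """
    if len(np.unique(ts.labels)) < 2:
        raise ValueError("training labels are single-class; cannot fit a classifier")
    n_rows, n_genes = ts.features.shape
    mtry = cfg.mtry if cfg.mtry is not None else max(1, int(np.sqrt(n_genes)))
    if mtry > n_genes:
        raise ValueError(f"mtry={mtry} exceeds n_genes={n_genes}")
    boot = cfg.bootstrap_size if cfg.bootstrap_size is not None else n_rows

    rng = np.random.default_rng(cfg.seed)
    tree_seeds = _spawn_seeds(cfg.seed, cfg.n_trees)
    all_rows = np.arange(n_rows)
    trees: list[DecisionTreeClassifier] = []
    inbag: list[np.ndarray] = []
    oob: list[np.ndarray] = []
    for t in range(cfg.n_trees):
        idx = rng.integers(0, n_rows, size=boot)
        mask = np.zeros(n_rows, dtype=bool)
        mask[idx] = True
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(ts.features[idx], ts.labels[idx])
        trees.append(tree)
        inbag.append(idx)
        oob.append(all_rows[~mask])
    return ForestModel(trees, inbag, oob, mtry, cfg)


def compute_mda(
    model: ForestModel, ts: TrainingSet, seed: int
) -> ImportanceReport:
    """Per-tree OOB permutation importance, averaged over trees.

    For tree t with OOB rows O_t and OOB accuracy a_t, shuffling gene j
    within O_t gives accuracy a_tj and a per-tree drop d_tj = a_t - a_tj.
    MDA_j averages d_tj over trees. A feature a tree never splits on leaves
    that tree's predictions untouched, so its d_tj is exactly 0 and is not
    recomputed. Trees with an empty OOB set are skipped with a warning.
    """
    n_genes = ts.n_genes
    x32 = np.ascontiguousarray(ts.features, dtype=np.float32)
    y = np.asarray(ts.labels)
    drops = np.zeros((model.n_trees, n_genes))
    per_tree_acc = np.full(model.n_trees, np.nan)
    perm_seeds = _spawn_seeds(seed, model.n_trees)
    used_trees = 0
    for t, (tree, oob) in enumerate(zip(model.trees, model.oob_indices)):
        if oob.size == 0:
            warnings.warn(f"tree {t} has an empty OOB set; skipped in MDA")
            logger.warning("tree %d has an empty OOB set; skipped in MDA", t)
            continue
        used_trees += 1
        x_oob = x32[oob].copy()
        y_oob = y[oob]
        base_pred = tree.predict(x_oob, check_input=False)
        a_t = float(np.mean(base_pred == y_oob))
        per_tree_acc[t] = a_t
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        rng = np.random.default_rng(perm_seeds[t])
        for j in used:
            saved = x_oob[:, j].copy()
            x_oob[:, j] = saved[rng.permutation(oob.size)]
            perm_pred = tree.predict(x_oob, check_input=False)
            drops[t, j] = a_t - float(np.mean(perm_pred == y_oob))
            x_oob[:, j] = saved
    if used_trees == 0:
        raise ValueError("every tree had an empty OOB set; cannot compute MDA")

    kept = ~np.isnan(per_tree_acc)
    mda = drops[kept].mean(axis=0)
    scaled = False
    if model.config.scale_mda:
        se = drops[kept].std(axis=0, ddof=0) / np.sqrt(used_trees)
        nonzero = se > 0
        mda = np.where(nonzero, mda / np.where(nonzero, se, 1.0), mda)
        scaled = True

    vote = model.oob_vote_predictions(ts.features)
    voted = vote >= 0
    oob_accuracy = float(np.mean(vote[voted] == y[voted])) if voted.any() else float("nan")
    return ImportanceReport(
        gene_ids=np.asarray(ts.gene_ids, dtype=object),
        mda=mda,
        per_tree_oob_accuracy=per_tree_acc,
        oob_accuracy=oob_accuracy,
        n_trees_used=used_trees,
        config=model.config,
        scaled=scaled,
    )


def select_genes(report: ImportanceReport) -> GeneSet:
    """Keep genes with MDA strictly > 0, best first (ties by gene id)."""
    keep = report.mda > 0
    if not keep.any():
        warnings.warn("no gene has MDA > 0; returning an empty gene set")
        logger.warning("no gene has MDA > 0; returning an empty gene set")
    return sorted_gene_set(report.gene_ids[keep], report.mda[keep])


def rfcell_select(
    x: ExpressionMatrix,
    cfg: ForestConfig | None = None,
    shared_permutation: bool = False,
) -> tuple[GeneSet, ImportanceReport]:
    """Full selection pipeline: permute -> stack -> forest -> MDA -> MDA>0.

    Fully determined by ``(x, cfg.seed)``: the permutation, the forest and
    the MDA shuffles all draw from sub-seeds of ``cfg.seed``.
    """
    cfg = cfg or ForestConfig()
    perm_seed, forest_seed, mda_seed = (int(s) for s in _spawn_seeds(cfg.seed, 3))
    ts = build_training_set(x, perm_seed, shared_permutation=shared_permutation)
    model = fit_forest(ts, ForestConfig(
        n_trees=cfg.n_trees,
        mtry=cfg.mtry,
        bootstrap_size=cfg.bootstrap_size,
        seed=forest_seed,
        scale_mda=cfg.scale_mda,
    ))
    report = compute_mda(model, ts, mda_seed)
    return select_genes(report), report


def consensus_select(
    x: ExpressionMatrix,
    cfg: ForestConfig | None = None,
    repeats: int = 10,
    min_count: int = 6,
) -> GeneSet:
    """Extension beyond the per-run rule: genes selected in >= min_count of
    ``repeats`` independent runs, scored by selection frequency."""
    cfg = cfg or ForestConfig()
    run_seeds = _spawn_seeds(cfg.seed, repeats)
    counts: dict[str, int] = {}
    for s in run_seeds:
        gs, _ = rfcell_select(x, ForestConfig(
            n_trees=cfg.n_trees, mtry=cfg.mtry,
            bootstrap_size=cfg.bootstrap_size,
            seed=int(s), scale_mda=cfg.scale_mda,
        ))
        for g in gs.gene_ids:
            counts[g] = counts.get(g, 0) + 1
    genes = [g for g, c in counts.items() if c >= min_count]
    freqs = [counts[g] / repeats for g in genes]
    return sorted_gene_set(genes, freqs)
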