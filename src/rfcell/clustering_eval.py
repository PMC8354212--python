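"""Clustering of selected gene subsets and the repeated-evaluation protocol.

Two in-repo clusterers mirror the harness's needs: k-means with seeded
restarts, and agglomerative (complete-linkage) clustering of the cell-cell
Spearman similarity matrix. The evaluation protocol runs a selector
repeatedly (the permutation-contrast selector is reseeded each repeat),
clusters the cells on the selected genes, and averages NMI/ARI against the
true labels — matching the convention of reporting the mean over 10 runs.

The high-mean-expression baseline ("Expr": keep the genes with the highest
average log1p expression) is provided for size-matched comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix, GeneSet, LabelVector, sorted_gene_set
from .metrics import adjusted_rand_index, nmi as nmi_score
from .rf_importance import ForestConfig, _spawn_seeds, rfcell_select

logger = logging.getLogger("rfcell")


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation protocol parameters.

    k defaults to the true number of clusters when None. seeds, when given,
    must have length repeats; otherwise repeat seeds are derived from seed.
    """

    k: int | None = None
    repeats: int = 10
    seed: int = 0
    seeds: tuple[int, ...] | None = None
    clusterer: str = "kmeans"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.repeats:
            raise ValueError("len(seeds) must equal repeats")
        if self.clusterer not in ("kmeans", "hclust"):
            raise ValueError(f"unknown clusterer {self.clusterer!r}")

    def run_seeds(self) -> np.ndarray:
        if self.seeds is not None:
            return np.asarray(self.seeds, dtype=np.int64)
        return _spawn_seeds(self.seed, self.repeats).astype(np.int64)


@dataclass(frozen=True)
class RunRecord:
    seed: int
    n_selected: int
    nmi: float
    ari: float
    failed: bool = False


@dataclass(frozen=True)
class EvalResult:
    per_run: tuple[RunRecord, ...]
    mean_nmi: float
    mean_ari: float
    selector: str
    clusterer: str


def expr_select(x: ExpressionMatrix, k_genes: int) -> GeneSet:
    """Top k_genes by mean log1p expression across cells, ties by gene id."""
    if not 1 <= k_genes <= x.n_genes:
        raise ValueError(f"k_genes must be in [1, {x.n_genes}], got {k_genes}")
    means = np.log1p(x.values).mean(axis=0)
    ordered = sorted_gene_set(x.gene_ids, means)
    return GeneSet(ordered.gene_ids[:k_genes], ordered.scores[:k_genes])


def spearman_similarity(x: ExpressionMatrix) -> np.ndarray:
    """m x m Spearman rank correlation between cells' expression profiles.

    Ties get average ranks. A cell constant across all genes has undefined
    rank correlation; its off-diagonal entries are set to 0 with a warning.
    """
    if x.n_genes < 2:
        raise ValueError("Spearman similarity needs at least 2 genes")
    ranks = rankdata(x.values, axis=1)
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cell(s) constant across genes; "
            "their similarities set to 0"
        )
        # substitute unit-variance noise-free placeholder to avoid 0/0,
        # then overwrite the affected rows/cols below
        ranks = ranks.copy()
        ranks[degenerate, 0] += 1.0
    s = np.corrcoef(ranks)
    if degenerate.any():
        s[degenerate, :] = 0.0
        s[:, degenerate] = 0.0
    np.fill_diagonal(s, 1.0)
    return s


def hierarchical_cluster(s: np.ndarray, k: int) -> np.ndarray:
    """Cut a complete-linkage tree on distance 1 - similarity into k clusters."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    m = s.shape[0]
    if not 2 <= k <= m:
        raise ValueError(f"k must be in [2, {m}], got {k}")
    dist = 1.0 - s
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dist, checks=False), method="complete")
    return fcluster(tree, t=k, criterion="maxclust") - 1


def kmeans_cluster(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Lloyd's k-means, 10 seeded restarts, best inertia kept."""
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if not 2 <= k <= m:
        raise ValueError(f"k must be in [2, {m}], got {k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed, algorithm="lloyd")
    return km.fit_predict(values)


def _cluster(x: ExpressionMatrix, clusterer: str, k: int, seed: int) -> np.ndarray:
    # Cells are clustered on log1p values: normalized expression is
    # heavy-tailed and untransformed k-means is dominated by a few genes.
    values = np.log1p(x.values)
    if clusterer == "kmeans":
        return kmeans_cluster(values, k, seed)
    sim = spearman_similarity(x)
    return hierarchical_cluster(sim, k)


def evaluate_selection(
    x: ExpressionMatrix,
    truth: LabelVector,
    selector: str = "rfcell",
    cfg: EvalConfig | None = None,
    forest_cfg: ForestConfig | None = None,
    expr_n_genes: int | None = None,
) -> EvalResult:
    """Run a selector repeatedly, cluster the selected genes, average NMI/ARI.

    selector: ``rfcell`` (reseeded each repeat), ``expr`` (top expr_n_genes
    by mean log1p expression; deterministic) or ``all_genes``. k defaults to
    the number of distinct true labels. Runs yielding an empty selection are
    recorded as failed and excluded from the means.
    """
    cfg = cfg or EvalConfig()
    forest_cfg = forest_cfg or ForestConfig()
    if len(truth) != x.n_cells:
        raise ValueError("truth labels not aligned to cells")
    if selector not in ("rfcell", "expr", "all_genes"):
        raise ValueError(f"unknown selector {selector!r}")
    if selector == "expr" and expr_n_genes is None:
        raise ValueError("expr selector requires expr_n_genes")
    k = cfg.k if cfg.k is not None else truth.n_distinct
    if k < 2:
        raise ValueError("need at least 2 clusters to evaluate")

    records: list[RunRecord] = []
    for run_seed in cfg.run_seeds():
        run_seed = int(run_seed)
        if selector == "rfcell":
            gs, _ = rfcell_select(x, ForestConfig(
                n_trees=forest_cfg.n_trees,
                mtry=forest_cfg.mtry,
                bootstrap_size=forest_cfg.bootstrap_size,
                seed=run_seed,
                scale_mda=forest_cfg.scale_mda,
            ))
            selected = list(gs.gene_ids)
        elif selector == "expr":
            selected = list(expr_select(x, expr_n_genes).gene_ids)
        else:
            selected = list(x.gene_ids)
        if len(selected) == 0:
            logger.warning("run seed=%d selected no genes; excluded from means", run_seed)
            records.append(RunRecord(run_seed, 0, float("nan"), float("nan"), failed=True))
            continue
        sub = x.subset_genes(selected)
        pred = _cluster(sub, cfg.clusterer, k, run_seed)
        records.append(RunRecord(
            run_seed,
            len(selected),
            nmi_score(pred, truth.labels),
            adjusted_rand_index(pred, truth.labels),
        ))
    ok = [r for r in records if not r.failed]
    if not ok:
        raise ValueError("every run produced an empty selection")
    return EvalResult(
        per_run=tuple(records),
        mean_nmi=float(np.mean([r.nmi for r in ok])),
        mean_ari=float(np.mean([r.ari for r in ok])),
        selector=selector,
        clusterer=cfg.clusterer,
    )
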