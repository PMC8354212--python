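# rfcell

Permutation-contrast random-forest gene selection for single-cell RNA-seq
clustering, with clustering-agreement metrics (NMI, ARI), k-means and
Spearman-similarity hierarchical clustering, a repeated-evaluation harness,
and a synthetic benchmark generator with known informative genes.

## The problem

Clustering scRNA-seq data is dominated by noise genes: of the 15,000–47,000
genes in a typical normalized expression matrix (CPM/TPM/RPKM/FPKM), only a
small subset varies with cell type. Selecting cell-type-informative genes
before clustering both reduces dimensionality and can improve cell-type
identification. `rfcell` implements a supervised selection strategy that
needs no labels: it manufactures its own negative class by permutation.

## The method

Given a cells × genes matrix **X** (m × n):

1. **Negative samples.** Shuffle each gene column of **X** independently to
   get **Z** (m × n). Each row of **Z** is a pseudo-cell with the exact
   per-gene marginals of the data but none of the gene–gene dependence that
   cell identity induces.
2. **Contrast classifier.** Stack **N** = [**X**; **Z**] (2m × n) with
   labels *y* = [1…1, 0…0] and train a random forest (500 trees,
   mtry = ⌊√n⌋, bootstrap of size 2m with replacement — the classical
   classification defaults).
3. **Importance.** For each tree *t* with out-of-bag (OOB) rows *O_t* and
   OOB accuracy *a_t*, permute gene *j* within *O_t* and recompute accuracy
   *a_tj*. The mean decrease accuracy is MDA_j = mean_t (a_t − a_tj).
4. **Selection.** Keep genes with MDA_j > 0 (strict).

A gene helps separate real cells from permuted ones only through structure
that permutation destroys — i.e., cluster-driven co-variation — so MDA is a
label-free score of cell-type informativeness.

Agreement between a clustering *U* and truth *V* is scored with
NMI(U,V) = 2 I(U;V) / (H(U) + H(V)) and the adjusted Rand index
ARI = (Index − E[Index]) / (Max − E[Index]) over the contingency table,
both implemented from first principles and oracle-tested.

## Worked example

```python
import rfcell

ds = rfcell.generate(rfcell.SyntheticConfig(seed=1))    # 200 cells x 1000 genes
gs, rep = rfcell.rfcell_select(ds.x, rfcell.ForestConfig(n_trees=500, seed=1))
print(f"selected {len(gs)} of {ds.x.n_genes} genes; "
      f"forest OOB accuracy {rep.oob_accuracy:.3f}")

cfg = rfcell.EvalConfig(repeats=10, seed=11)            # 10-repeat protocol
for sel, kw in [("rfcell", {}), ("all_genes", {}),
                ("expr", {"expr_n_genes": len(gs)})]:
    res = rfcell.evaluate_selection(ds.x, ds.truth, sel, cfg, **kw)
    print(f"{sel:9s}  mean NMI {res.mean_nmi:.3f}  mean ARI {res.mean_ari:.3f}")
```

prints

```
selected 352 of 1000 genes; forest OOB accuracy 0.065
rfcell     mean NMI 0.455  mean ARI 0.437
all_genes  mean NMI 0.664  mean ARI 0.703
expr       mean NMI 0.277  mean ARI 0.289
```

On this benchmark — dense log-normal expression with a uniform 30% dropout —
the selection beats the highest-mean-expression baseline (`expr`) but not
the all-genes baseline, and the forest's OOB accuracy collapses far below
chance. Both effects are real properties of the permutation contrast on
dense tie-free data, analysed in `docs/methods.md`: every real value has an
exact duplicate in the permuted class, so fully grown trees memorize
value identity instead of structure. On sparse marker-style data, where the
cluster signal lives in zero/nonzero patterns as it does in real scRNA-seq,
the same pipeline ranks informative genes with AUROC ≳ 0.87 and recovers
≥ 80% of them (see `tests/test_rf_importance.py`).

A command-line interface mirrors the API:

```bash
rfcell simulate --cells 200 --clusters 3 --seed 1 --out sim/
rfcell select   --input sim/X.csv --seed 1 --trees 500 --output genes.tsv
rfcell evaluate --input sim/X.csv --labels sim/labels.csv \
                --selector rfcell --clusterer kmeans --repeats 10 \
                --seed 1 --report report.json
rfcell metrics  --pred pred.csv --truth truth.csv
```

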