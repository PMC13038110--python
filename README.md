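# duodecon

Dual-branch deep deconvolution of bulk RNA-seq: for every bulk sample the
model predicts both the cell-type proportion vector **p** and a
*per-sample* matrix **G** of cell-type-specific gene expression profiles
(GEPs), under the linear mixing model **G p = b**. Unlike signature-based
deconvolution, the per-sample **G** lets downstream analyses ask how a
given cell type's expression differs between patients or conditions — the
package includes the full combinatorial cell-state subtyping framework
that exploits this: binary cell states per cell type, enumeration of all
conjunction-style patient-group definitions, log-rank survival screening
with Benjamini–Hochberg control, IoU-based merging of near-duplicate
definitions, and majority-vote consensus grouping with external-cohort
transfer.

The intended users are computational biologists with (a) an annotated
scRNA-seq reference from the same tissue context and (b) bulk RNA-seq
cohorts — optionally with survival metadata — who want cell-type-resolved
expression and prognostic patient subtypes out of the bulk data.

## Model

A bulk vector of g genes (log2 counts-per-million) is lifted by a linear
layer into a 4096-dimensional shared feature vector. A 5-layer MLP
(4096, 1024, 256, 64, c; SiLU activations; softmax output) predicts
proportions on the simplex. A 1-D U-Net (4 down blocks that double
channels and halve length, 4 up blocks that mirror them with skip
concatenation) predicts the GEP matrix; the c channels of its output head
index cell types and a per-channel linear map projects back onto the g
genes. Both branches are trained jointly on simulated pseudobulk samples
with the weighted loss

    L = lambda_p * MSE(p_hat, p) + lambda_G * MSE(G_hat, G)

where the GEP term runs over cell types actually present in each sample.
Training pairs are simulated from the reference: Dirichlet proportions
(alpha = 25 for even compositions, alpha = 7 on one type for dominant
ones), multinomial cell counts, cells averaged in raw count space so the
identity b = sum_t p_t G[:, t] holds exactly, then CPM/log2 normalization.
The network and its backpropagation are implemented in NumPy
(`duodecon.nn`), gradient-checked against finite differences.

Everything is documented in detail in [docs/methods.md](docs/methods.md).

## Worked example

The whole loop — generate a planted two-condition reference, select
markers, simulate pseudobulk, train, deconvolve held-out samples — is
wired in `duodecon.workflows.parameter_recovery`:

```python
from duodecon.workflows import parameter_recovery

report, model, gene_list = parameter_recovery(seed=1)
print("genes:", report.n_genes)
print("proportion CCC:", round(report.proportion_ccc, 4))
print("per-type L1:", {t: round(v, 4) for t, v in report.proportion_l1_per_type.items()})
print("per-type GEP r:", {t: round(v, 4) for t, v in report.gep_pearson_per_type.items()})
print("condition shift r (DEG panel):", round(report.condition_shift_pearson, 4))
```

On one CPU this takes about 18 minutes (12 training epochs at the
default architecture) and prints:

```
genes: 952
proportion CCC: 0.9815
per-type L1: {'type0': 0.0394, 'type1': 0.0189, 'type2': 0.0175,
              'type3': 0.0203, 'type4': 0.0161, 'type5': 0.0163}
per-type GEP r: {'type0': 0.9521, 'type1': 0.9488, 'type2': 0.9504,
                 'type3': 0.9471, 'type4': 0.9504, 'type5': 0.9453}
condition shift r (DEG panel): 0.7384
```

Reading these numbers: predicted cell-type compositions of 200 held-out
pseudobulk samples agree with the realized sampling fractions at Lin's
CCC 0.98 with mean absolute error below 0.04 for every type; each type's
predicted expression profile correlates with its sampled ground truth at
r ≈ 0.95 (over samples where the type exceeds 4% of cells, where the
ground-truth profile is meaningful); and the predicted
between-condition expression differences over the planted condition-DEG
panel track the truth at r ≈ 0.74 — the model attributes condition
shifts to the right cell types from bulk data alone.

A command-line interface mirrors the library:

```bash
duodecon make-fixtures --out fixtures --seed 3
duodecon select-features --reference fixtures/reference.h5ad --out genes.tsv
duodecon train --reference fixtures/reference.h5ad --genes genes.tsv --out model.npz
duodecon deconvolve --checkpoint model.npz --bulk cohort.tsv --out deconv/
duodecon subtype --deconv deconv/ --survival survival.tsv --out subtypes/
```

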