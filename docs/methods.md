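# Methods

## The deconvolution model

A bulk RNA-seq sample over a fixed gene list is modeled as a linear mixture
of cell-type-specific expression: with per-type gene expression profiles
(GEPs) collected in **G** ∈ R^{g×c} and proportions **p** on the
c-simplex, the bulk vector satisfies **G p = b**. Classical deconvolution
estimates only **p** against a fixed signature matrix; here a network
predicts *both* **p** and a per-sample **G**, so that the same cell type may
express differently in different samples (conditions, patients).

The network takes the log2 CPM bulk vector (g genes) and lifts it with one
linear layer into a shared feature vector of width `feature_dim` (default
4096). Two heads consume the shared features:

* **Proportion head** — a 5-layer MLP with widths 4096, 1024, 256, 64, c and
  SiLU activations between the linear layers; a terminal softmax constrains
  the output to the simplex (configurable off).
* **GEP head** — the features, viewed as a length-4096 sequence with one
  channel, pass through a 1-D U-Net: a stem convolution lifts to
  `base_channels` (default 8); each of 4 down blocks is a max pool followed
  by two (convolution, batch norm, ReLU) rounds, doubling channels and
  halving length (8→16→32→64→128 over 4096→…→256); each of 4 up blocks is a
  kernel-2 stride-2 transposed convolution followed by the same two rounds,
  with skip concatenation from the matching down level. A head convolution
  maps to c channels — one per cell type — and a per-channel linear layer
  (shared across channels) projects each length-4096 channel onto the g
  genes, followed by ReLU so predicted expression is non-negative.

The U-Net literature leaves two details open for this 1-D regression use:
how the length-`feature_dim` output becomes a length-g profile, and whether
skip connections are present. We use a shared per-channel linear projection
(the minimal addition that produces a c × g output) and keep skip
connections (the defining property of a U-Net). Batch normalization uses
batch statistics during training and exponentially averaged running
statistics at inference, so inference is deterministic per sample and
independent of batch composition.

The network, its backward pass, and the Adam optimizer are implemented
directly in NumPy (`duodecon.nn`): channels-last layout makes every
convolution a single matrix product over stacked shifted views, and all
parameters live in one contiguous buffer so optimizer updates are a few
vectorized passes. Every layer's gradients are verified against central
finite differences in float64, as is the assembled model.

## Training data: pseudobulk simulation

Training pairs come from an annotated single-cell reference. Cells are
split 8:1:1 into train/validation/test, stratified by cell type so every
type is present in every split (the stratification is this package's
choice; it guarantees simulation never lacks a type). For each sample:

1. a proportion vector is drawn from a Dirichlet — symmetric α=25 ("even"
   mode) or α=7 on one uniformly chosen type with 1 elsewhere ("dominant"
   mode, producing one dominant cell type);
2. per-type cell counts are multinomial with `cells_per_sample` trials
   (default 500); cells are drawn uniformly *with replacement* within type;
3. the pseudobulk is the average raw-count vector over all sampled cells,
   and the ground-truth GEP columns are per-type averages over the same
   cells, so the count-space identity b = Σ_t p_t G[:,t] holds exactly with
   p the realized multinomial fractions;
4. inputs and GEP targets are library-normalized to counts-per-million and
   log2(x+1)-transformed. Normalization happens on the full gene axis
   before the model's gene list is cut out, mirroring how a real bulk
   library is normalized on the whole transcriptome.

With several references, a quarter of the training samples (configurable)
pool cells across all references, which emulates training against mixed
batches. Cell types absent from a sample get a zero GEP column and are
masked out of the loss. Averaging raw counts before a single normalization
(rather than averaging per-cell-normalized expression) is a deliberate
choice: it preserves the exact count-space linearity invariant and keeps
predicted GEPs in the same log2 CPM space as the inputs.

## Feature selection

Per cell type, a one-vs-rest two-sided Wilcoxon rank-sum test on log2 CPM
expression, Benjamini–Hochberg adjusted within that cell type's family;
genes pass with adjusted p < 0.1 and positive log fold change (difference
of mean log2 expression), are ranked by log fold change (ties broken by
gene identifier for reproducibility), truncated to `top_n` (default 285),
and unioned across cell types and references. An externally supplied list
of genes of interest — e.g. condition markers — can be unioned in; the
model then trains and predicts on the same list.

## Loss and optimization

The loss is λ_p·MSE(p̂, p) + λ_G·MSE(Ĝ, G), the GEP term averaged over
present-type columns only. The weights exist to balance the two terms:
proportion MSE is of order 10⁻³–10⁻² while log2-space GEP MSE is of order
10, so the defaults are λ_p = 3000, λ_G = 1. The balance matters for the
*shared* feature extractor: under Adam the per-branch parameters are
rescaled adaptively, but the extractor receives the sum of both branches'
gradients, and a strongly GEP-dominated sum destabilizes the proportion
head (in the worst case the softmax saturates at a vertex and its gradient
vanishes). Optimization is Adam at learning rate 1e-4 with batch size 64;
the best-validation parameters are kept, with early stopping on patience.
Training aborts with a diagnostic on non-finite loss.

Two initialization choices matter for how fast the GEP head becomes
useful. By default the trainer seeds the final projection's per-gene bias
with the training set's mean GEP profile and shrinks the projection's
weights by 0.1, so the network's initial output *is* the cohort-mean
profile and optimization is spent on residual, sample-specific expression
from the first step (the analogue of initializing a classifier's output
bias to the class priors). Without this, early training re-learns the
static gene baseline through the network weights, and small
input-dependent components — notably between-condition expression shifts,
which contribute on the order of 1% of the GEP loss — emerge only after
far more epochs. Learning rates above ~1e-4 are counterproductive here:
they speed the GEP branch but saturate the softmax proportion head, whose
gradient then vanishes.

## Evaluation metrics

For ground truth x and prediction y (population moments throughout):

* L1 = mean |y−x|;
* Pearson ρ;
* Lin's concordance ρ_c = 2ρσ_xσ_y / (σ_x² + σ_y² + (μ_x−μ_y)²), which
  penalizes location and scale shifts on top of decorrelation;
* linear-fitting R² = 1 − Σ(y−x)² / Σ(x−x̄)², so a constant prediction at
  the ground-truth mean scores exactly 0 (the denominator is the squared
  deviation sum; an unsquared denominator would not have this property).

### How recovery is measured on simulated data

Two evaluation definitions are deliberately noise-aware. First, the
per-type GEP correlation pools only samples in which the type makes up at
least 4% of the sampled cells (20 of 500 at the default). The reason is a
ceiling argument: a sample's "ground-truth" profile for a type drawn with
a handful of cells is an average over those few cells, and even the true
expected profile — computable exactly on synthetic data — correlates with
such targets at only 0.87–0.97 when all present samples are pooled, versus
0.99 under the 4% floor. Below the floor the statistic measures sampling
noise, not prediction quality. Second, the between-condition shift
correlation is computed over the condition-DEG panel (the planted
condition DEGs, all cell-type columns): pooling thousands of genes with no
between-condition signal dilutes the statistic with rows where both truth
and prediction are zero plus noise. Restricting rows keeps the hard part —
attributing each shift to the correct cell type — while measuring the
signal that exists; the all-gene value is reported alongside.

## Cell-state patient subtyping

Given per-patient deconvolution output:

* **Proportion subtypes.** PCA on the proportion matrix; Leiden clustering
  in PCA space with the resolution bisected to a requested cluster count;
  transfer to an external cohort by k-nearest-neighbor majority vote (k=5)
  in the same PCA space, with deterministic smallest-label tie-breaks.
* **Cell states.** Per cell type, patients are Leiden-clustered on that
  type's predicted GEPs with the resolution bisected until exactly two
  clusters emerge (falling back to a 2-way Ward cut for degenerate
  profiles, logged); state 0 is the larger group.
* **Definitions.** Every conjunction of k chosen types and states
  (k = 1…c) defines the matching patients as one group and the rest as the
  other; definitions inducing the same partition are counted once. With all
  2^c state combinations populated this yields 3^c − 1 − c distinct
  definitions (722 for c = 6: the two complementary k=1 definitions of each
  type collapse, and no larger subcube is complementary to another).
* **Screening.** A two-group log-rank test per definition (groups smaller
  than 5 patients or with no events are skipped), BH-adjusted across all
  tested definitions, kept at adjusted p < 0.05.
* **Merging.** Pairwise similarity of screened definitions is the IoU of
  their smaller groups, maximized over the two orientations of the second
  definition; similarities ≥ 0.8 define graph edges and connected
  components are merged: within a component, each definition's two
  indicator orientations are aligned to the smallest-p definition by
  Hamming distance (exact ties keep the first orientation, logged); a
  patient joins a consensus group only when more than (n+1)/2 of the n+1
  aligned definitions agree, otherwise they are explicitly unresolved; of
  the two candidate orientations the one with fewer unresolved patients is
  kept.
* **Survival patterns.** Each component consensus is labeled favorable or
  unfavorable by comparing restricted mean survival of its distinguished
  group against the rest (median survival is available as an alternative);
  same-direction consensuses are merged by one more round of majority
  voting. Output: favorable group, unfavorable group, remainder; patients
  claimed by both directions go to the remainder, logged.
* **External transfer.** Per direction, group-vs-rest rank-sum DEGs on the
  training cohort's bulk expression; a 1-component PCA per cohort on those
  genes (the per-cohort component sign is aligned by the correlation of
  gene loadings, since a 1-D PCA sign is arbitrary); logistic regression on
  the training component scores, applied to the test cohort's scores.

## Synthetic references and survival

The generator plants known structure so that every stage can be tested
against ground truth. Counts are negative-binomial via a gamma–Poisson
mixture with a single shared overdispersion φ (var = m + φm², default 0.3,
a typical droplet-scRNA-seq magnitude); per-gene baseline means are
lognormally spread (σ=1) around `baseline_mean` (default 2 expected counts
per gene). Each cell type receives `n_markers_per_type` disjoint marker
genes whose mean is multiplied by `marker_fold_change`; a two-condition
design additionally shifts `n_condition_degs` disjoint genes per type by
`condition_fold_change` in the second condition. Survival times are
exponential with per-group hazard multipliers and independent censoring
(probability `censor_rate`; censored times uniform on (0, event time)).

What the generator does *not* emulate: cross-platform batch effects,
gene-length bias, read-level noise, ambient RNA, doublets, or correlated
gene modules beyond the planted ones. Passing tests on these fixtures
demonstrate that the implementation recovers planted structure under the
model's own assumptions, not that the method resolves real tissue.

## Reference experiment scales

The parameter-recovery experiment (`duodecon.workflows.parameter_recovery`)
uses a 6-type, 2000-gene reference with 500 cells per type, fold-8 markers,
and fold-4 condition DEGs across two conditions; rank-sum selection at
top_n = 250 per type yields a working list of ~950 genes. Training uses
2000 pseudobulk samples (even/dominant modes × two conditions in equal
shares), validation and test 200 each with the same composition, and the
default architecture and optimizer for 12 epochs. On held-out test samples
this recovers proportions at CCC ≥ 0.9 with per-type mean L1 ≤ 0.05,
per-type GEP correlation ≥ 0.9 (4%-floor pooling, above), and
between-condition expression shifts over the condition-DEG panel
correlated with the planted truth at r ≥ 0.7. These scales are the
package's desk-scale reference configuration; larger references and
training sets only help.

## Numerical and degenerate-input conventions

* Library normalization raises on an all-zero profile rather than
  returning zeros silently.
* `ccc`/`pearson` raise on constant vectors; `r2_fit` raises on constant
  ground truth.
* Dirichlet draws use gamma variates normalized row-wise; `c=1` returns the
  trivial [1.0].
* Leiden resolution searches are geometric bisections with a bounded
  iteration count; unreachable cluster counts raise (proportion subtypes)
  or fall back to Ward (cell states).
* All generators and the trainer are seeded; identical seeds give
  bit-identical outputs.

## Known limitations

* The NumPy implementation is single-process and CPU-bound; at the default
  architecture a 2000-sample epoch costs on the order of minutes.
* The GEP head supervises only types present in a sample; proportions for
  absent types are driven to zero by the proportion loss alone.
* Survival screening treats definitions as exchangeable hypotheses in one
  BH family; the heavy overlap between conjunction definitions makes the
  adjustment conservative rather than exact.
* The consensus stage follows its matching and voting rules exactly,
  including the tie conventions; alternative orderings of equal-p definitions
  within a component could change orientations (not memberships).
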