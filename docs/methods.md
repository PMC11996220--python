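# Methods

## Model

`ConstrainedPathwayClassifier` is a three-input neural classifier for
CN / MCI / AD status. Per-gene SNP aggregates and gene expression each
feed a subnetwork of `depth` (default 3) sparsely connected layers whose
weights are frozen 0/1 connectivity masks derived from a pathway
hierarchy; a 45-node clinical block bypasses the subnetworks. The
concatenated representation passes through batch normalisation, a
19-unit linear layer, dropout at rate 0.597, an 8-unit ReLU layer (both
dense layers L2-regularised) and a 3-way softmax.

Assumptions baked into this design:

- **Pathway nodes are signed sums.** The default subnetwork activation is
  the identity, so a pathway node's activation is exactly the sum of its
  constrained inputs and the whole subnetwork is the masked matrix
  product `x·M₀·M₁·⋯`. A `tanh` option exists for bounded activations.
- **The masks are the weights.** Frozen layers carry no biases and the
  weight value on every existing edge is 1.0 — the constraint is purely
  structural. Consequently training touches only batch-norm scale/shift
  and the three head layers, which the gradient-isolation tests assert.
- **Hierarchy layering.** Pathway levels are assigned by distance from a
  root (a pathway appearing as a parent but never as a child):
  `level = depth − min(dist, depth−1)`. Root-adjacent pathways occupy the
  top layer; anything deeper than the cut collapses onto level 1, the
  gene-adjacent layer. Gene membership is up-propagated over each
  level-1 pathway's descendant closure. Level-1 pathways with no
  connected genes are dropped, as are higher nodes left without incoming
  edges; multi-parent pathways keep all parent edges (the hierarchy is a
  DAG, not a tree). With an empty relations table every pathway is
  unreachable and sits at level 1. Unannotated genes keep all-zero mask
  rows so the input axis always matches the supplied gene list.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) minimises categorical
cross-entropy plus L2 penalties. The learning rate follows a staircase
exponential schedule, `0.008 · 0.96^⌊t/17⌋` at optimiser step *t* —
"every 17 steps" is read as discrete drops, which the schedule tests pin
at steps 0, 17 and 34. Batch size 32, at most 120 epochs, early stopping
on validation loss with patience 10 and best-weight restoration
(patience and the L2 coefficient 0.01 are configurable; they are
protocol details the published configuration leaves open). Batch-norm
follows the common 0.99-momentum / 1e-3-epsilon convention.

The preprocessing chain is ordered: split assignment → clinical
categorical encoding (integer codes; non-binary categoricals one-hot
expanded, so the expanded clinical width can exceed 45) → drop features
with ≥60% missingness *on training rows* → kNN imputation (k = 5) fitted
on the training table (partial-distance Euclidean metric over mutually
observed features, continuous columns standardised; distance-weighted
mean for continuous targets, mode for categorical) → block concatenation
→ SMOTE on the concatenated training block (synthetic rows are convex
combinations of same-class neighbour pairs, so all three modalities stay
aligned) → min-max scaling fitted on the balanced training block
(validation/test transformed unclipped; constant features map to 0).
Every fitted statistic uses training rows only. Missing genotype codes
contribute 0 to a gene's additive sum (a conservative no-signal default);
additive aggregation is the unweighted sum.

Evaluation defines per-class TP/TN/FP/FN one-vs-rest; precision is
TP/(TP+FP) — the specificity-like formula that sometimes appears in
print, TN/(TN+FP), is not precision and is not used. Headline numbers are
macro averages with per-class values always reported; AUC is one-vs-rest
on softmax scores, and a class absent from the test set yields an
undefined AUC excluded from the macro.

## Shapley explanation

The explainer is model-agnostic permutation sampling: for each sampled
feature ordering (paired with its reverse — antithetic sampling halves
variance at no cost) and one background row per draw, features switch
from background to target value one at a time and the change in each
class probability is the marginal contribution. Per draw the telescoping
sum reconstructs `f(x) − f(b)` exactly, so local-accuracy residuals
reflect only the sampling of background rows and shrink with budget.
`permutations="exact"` enumerates all n!·|background| walks, which the
tests verify equals the 2ⁿ-coalition brute force. The background is 100
training rows; attributions default to the test split; features are
ranked per class and modality by mean absolute attribution with
lexicographic tie-breaks.

**Limitation — gene-level attribution under frozen masks.** Because a
subnetwork is a fixed linear map, the model's output depends on a gene
only through path-weighted pathway sums. Genes sharing a connectivity
profile are exchangeable to the model, and a gene's attribution scales
with its mask path multiplicity and its deviation from the background —
not with its true class-relevance. On synthetic cohorts the planted
genes gain only a ~2× deviation-spread advantage over null genes, while
path weights vary more than that across genes, so the per-modality
top-20 lists recover roughly half of the planted features (union over
the three class lists; per-class lists recover less, worst for MCI,
whose one-vs-rest signal is weakest for monotone effects). This is a
property of mask-constrained sum architectures, not of the estimator:
the same lists computed at 4× the sampling budget are unchanged.

## Intermediate activations and statistics

Pathway-node activations are the forward pass truncated at a level;
class-grouped samples are screened with the tie-corrected Kruskal-Wallis
test (χ² reference, groups−1 df). Raw per-node p-values are reported by
default (no multiplicity correction, matching the per-node reporting
convention); a Benjamini–Hochberg flag can be added downstream from the
returned table. Density summaries use a Gaussian KDE with Silverman's
bandwidth on a shared grid. Cohort characterisation offers chi-square
contingency tests (no continuity correction — required to reproduce
p = 0.012 from the published sex counts), one-way ANOVA reconstructable
from per-group means/SDs/sizes alone (algebraically identical to
raw-data ANOVA), and Kruskal-Wallis for skewed scores.

## Synthetic cohorts

The generator emulates the structure of the reference cohort: 212 CN /
317 MCI / 97 AD; 300 genes per omic at working scale (10,151 reproduces
the full-scale input width 2·10,151 + 45 = 20,347); SNP gene-aggregates
are sums over 1–8 variants per gene of Binomial(2, MAF) draws with MAF ∈
(0.05, 0.5); expression is Gaussian on a log-microarray-like scale
(means 5–10, SDs 0.8–1.2). Ten planted genes per omic receive a mean
shift of `effect_size` (default 2.0) pooled SDs per class step. The
45-column clinical schema follows published three-group summary moments
for the standard instruments (MMSE, CDRSB, ADAS, RAVLT, Ecog, FDG/AV45
uptake, CSF tau, MRI volumes, demographics), so cognitive scores degrade
monotonically CN → MCI → AD; two garbled printed SDs (entorhinal MCI,
MOCA AD) were replaced by values plausible for the instrument. 10%
missingness is applied to the features that are sparse in practice
(biomarkers, Ecog, trail-making). `clinical_effect` scales the class
separation of clinical means *and* SDs toward the CN values; the null
calibration uses `effect_size=0, clinical_effect=0` because
class-dependent variances alone are learnable signal. The generator does
not emulate linkage disequilibrium, expression covariance or
array-normalisation artefacts, so passing tests demonstrate pipeline
correctness and calibration, not real-data performance.

Perturbation validation multiplies selected feature values by `1 − u`,
`u` uniform per subject in a configured range (20–30% for omics, 1–25%
for cognitive scores), for a without-replacement draw of half the CN
pool by default, checks distribution preservation with two-sample KS
tests, and reruns the identical pipeline before/after. The direction
check (amplifying planted associations must not lower macro AUC) is run
on a probe cohort calibrated near the published operating regime
(`effect_size=0.8, clinical_effect=0.2`, unperturbed macro AUC ≈ 0.89)
with the delta averaged over three training seeds: at the default
conditions the model saturates (AUC ≈ 0.999) and the comparison
degenerates into optimiser noise of ±1e-4.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds; the CLI
fans one global seed out to stages by fixed offsets. Constant features
min-max-scale to 0; a sample with every clinical feature missing is an
error rather than an imputation target; kNN neighbours never include the
row being imputed; softmax is computed with max-subtraction; a non-finite
loss aborts training with a diagnostic. Gene symbols are matched
case-sensitively after whitespace trimming (a case-folding flag exists).
Parameter accounting walks the layers: trainable = batch-norm scale/
shift + head weights and biases; non-trainable = mask nonzeros + batch-
norm moving statistics; counts are reported per subnetwork and combined
because the published per-subnetwork figure is ambiguous between one
subnetwork and both. The published trainable-parameter total cannot be
reconciled from the published layer widths alone, so parameter counts
are verified against the layer walk, not against that figure.
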