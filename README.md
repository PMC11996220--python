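# pathwaynet

Pathway-constrained multimodal classification of Alzheimer's disease
status (cognitively normal / mild cognitive impairment / AD dementia)
from blood-derived genotype aggregates, gene expression and clinical
features — with Shapley-value explanation, intermediate pathway-activation
analysis, cohort statistics, and a synthetic-cohort validation harness.

## Who this is for

Researchers building interpretable multi-omics classifiers for
neurodegenerative disease. Instead of a dense network, the two omics
inputs pass through **frozen sparse subnetworks** whose layers are
pathways from a hierarchically organised knowledgebase (Reactome-style:
a GMT gene-set file plus a parent–child relations table). Connectivity is
a stack of binary masks:

- `mask[0][g, p] = 1` iff gene *g* is annotated to level-1 pathway *p*
  or to any pathway in *p*'s descendant closure (membership
  up-propagation);
- `mask[l][p, q] = 1` iff pathway *q* is a parent of *p*.

The subnetwork weights **are** these 0/1 masks and are never trained, so
under the default identity activation a subnetwork output is the masked
matrix product `x · M₀ · M₁ · M₂`: each pathway node is the signed sum of
its constrained inputs. The two subnetwork tops are concatenated with the
clinical block and classified by a small trainable head:

```
concat → BatchNorm → Dense(19, linear, L2) → Dropout(0.597)
       → Dense(8, ReLU, L2) → Dense(3, softmax)
```

Training: Adam on categorical cross-entropy, learning rate
`0.008 · 0.96^⌊t/17⌋` (staircase, per optimiser step), batch size 32, at
most 120 epochs, early stopping on validation loss (patience 10, best
weights restored). The preprocessing chain is part of the protocol:
additive SNP codes (0/1/2) summed per gene, clinical features with ≥60%
training missingness dropped, kNN imputation (k = 5) fitted on the
training split, a stratified 56/14/30 train/validation/test split, SMOTE
class balancing of the training block, and min-max scaling fitted on
training rows.

## Worked example

```python
from pathwaynet import SyntheticCohortConfig, generate_cohort, train_and_evaluate
from pathwaynet.simulate import default_masks

cfg = SyntheticCohortConfig(seed=1)        # 212 CN / 317 MCI / 97 AD, 300 genes
cohort = generate_cohort(cfg)              # genotype + expression + 45 clinical
mask_snp, mask_expr = default_masks(cfg)   # 3-level pathway DAG → 0/1 masks

model, processed, report = train_and_evaluate(cohort, mask_snp, mask_expr, seed=1)
print(f"accuracy {report.accuracy:.3f}  macro AUC {report.macro_auc:.3f}  "
      f"macro F1 {report.macro_f1:.3f}")
```

prints

```
accuracy 0.984  macro AUC 0.998  macro F1 0.987
```

on the held-out test split (188 samples): the cohort plants a
2-pooled-SD-per-class-step effect on 10 genes per omic plus clinically
realistic cognitive-score gradients, and the constrained model recovers
that signal almost perfectly. `report.per_class` holds per-class TP/TN/
FP/FN, precision, recall, F1 and one-vs-rest AUC;
`pathwaynet.count_parameters(model)` reports 1,487 trainable and 1,376
frozen subnetwork parameters for this configuration.

The same pipeline is scriptable from the shell:

```bash
pathwaynet simulate --seed 1 --out cohort/
pathwaynet train    --seed 1 --data cohort/ --gmt cohort/pathways.gmt \
                    --relations cohort/relations.tsv --out run/
pathwaynet explain  --seed 1 --data cohort/ --gmt cohort/pathways.gmt \
                    --relations cohort/relations.tsv --out shap/
```

Other subcommands: `build-masks`, `preprocess`, `evaluate`,
`activations` (per-pathway-node Kruskal-Wallis screening),
`cohort-stats` (Table-1 style group summaries) and `validate-sim`
(perturbation-based robustness run).

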