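# mugsel — mutation-guided gene selection for cancer-type classification

`mugsel` implements a gene-selection method for expression-based cancer-type
classification that transfers information from DNA mutation profiles. The idea:
the genes whose *mutations* best discriminate cancer types are a good feature
list for classifying the same types from *expression* (FPKM) data — every step
is disease-specific, and no curated gene signature is needed.

It is aimed at computational-biology practitioners working with paired
cohorts (e.g. TCGA-style data where each patient has both a somatic VCF and an
FPKM expression profile) who want a data-driven alternative to classical
selectors (mutual information, mRMR, ReliefF) and curated collections
(Hallmark-style GMT unions).

## The method

Patients are treated as documents and genes as terms. From one VCF per sample,
a sample × gene mutation-count matrix is assembled (variant → gene by
positional containment). Each count is weighted with the supervised
**BM25-tf-rf** scheme:

```
w(i, g) = bm25_tf(tf_ig, dl_i) × rf_g

bm25_tf = (k1 + 1) · tf / (k1 · (1 − b + b · dl/avgdl) + tf)      k1=1.2, b=0.75
rf      = log2(2 + a / max(1, c))
```

where `tf` is the mutation count of gene *g* in patient *i*, `dl` the patient's
total mutation count, `avgdl` its cohort mean, and `a` / `c` the number of
target-class / rest samples carrying at least one mutation in *g* (one-vs-rest
per cancer type). Genes are then ranked per class by an **effectiveness
score** — either the absolute coefficient of a one-vs-rest logistic regression
on the weighted matrix (`coef`, default) or the class-mean weighted value
(`rf_mass`) — and the union of each class's top-*k* genes becomes the feature
list for the expression matrix. Classification is L2-regularized logistic
regression under stratified 5-fold cross-validation, reported as micro-averaged
accuracy, F1, one-vs-rest FPR, micro ROC-AUC and multiclass MCC (mean ± SD over
folds, in percent).

Baselines implemented for comparison: mutual-information top-K, greedy mRMR
(MID/MIQ), multiclass ReliefF, and GMT gene-set unions.

## Worked example

The synthetic cohort generator produces a paired cohort (3 classes × 50
samples, 2,000 genes, 30 planted genes per class that are both preferentially
mutated and differentially expressed in their class):

```python
from mugsel import (CohortSpec, SelectorSpec, cross_validate, generate,
                    score_effectiveness, top_k_union, weight_matrix)

counts, expression, truth = generate(CohortSpec(seed=1))
tables = [score_effectiveness(weight_matrix(counts, truth.labels, cls),
                              truth.labels, method="coef", seed=1)
          for cls in ("breast", "lung", "kidney")]
union = top_k_union(tables, 60)            # 144 genes for seed 1

base = cross_validate(expression, truth.labels, SelectorSpec(method="all"),
                      k=5, seed=1)
sel = cross_validate(expression, truth.labels,
                     SelectorSpec(method="fixed", genes=union,
                                  params={"name": "vcf_effective"}),
                     k=5, seed=1)
print(base.table_row())
print(sel.table_row())
```

prints (selector, feature count, then accuracy / F1 / ROC-AUC / FPR / MCC as
`mean ±SD` percent):

```
all                 2000   94.67 ±3.40  94.67 ±3.40  99.18 ±0.76  2.67 ±1.70  92.27 ±5.00
vcf_effective:144    144   99.33 ±1.33  99.33 ±1.33  99.99 ±0.02  0.33 ±0.67  99.03 ±1.94
```

The 144-gene mutation-derived list matches or beats the 2,000-gene baseline on
every metric — the mutation signal has transferred to the expression features.

The same flow is available from the shell:

```bash
mugsel simulate --out cohort --seed 1
mugsel count --vcf-dir cohort/vcfs --genes cohort/genes.bed --out counts.tsv
mugsel select --counts counts.tsv --labels cohort/labels.tsv --method coef --k 60 --out-dir sel
mugsel compare --expr cohort/expression.tsv --labels cohort/labels.tsv \
    --selectors all --selectors genes:sel/selected_genes.txt:vcf_effective \
    --seed 1 --out table.tsv
mugsel end-to-end --out run1 --seed 1     # everything above in one run directory
```

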