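# Methods

## Model and procedure

`mugsel` treats a patient's somatic variant set as a bag of gene-level events
and borrows the document/term machinery of information retrieval. The pipeline
runs in five stages.

**1. Mutation counting.** One VCF per sample is reduced to a sample × gene
count matrix. A record is assigned to every gene whose 1-based inclusive
interval contains the record's POS; END/SVLEN are ignored, so structural
variants count once at their start. Records outside all genes are dropped and
summarized in the log; a record inside two overlapping genes increments both
(logged). Counting defaults to one increment per record (`per_variant`) so
that term-frequency saturation is meaningful; a `per_gene_binary` presence
mode is available because the counting granularity of the original gene lists
is not documented. FILTER and QUAL are ignored by default (`pass_only`
restricts to PASS). Chromosome names are normalized by stripping a leading
`chr`, and Ensembl version suffixes are stripped from gene IDs everywhere on
ingest, because expression and annotation sources routinely disagree on both.

**2. BM25-tf-rf weighting.** Each count tf of gene g in patient i becomes

    bm25_tf = (k1+1)·tf / (k1·(1 − b + b·dl/avgdl) + tf),

with dl the patient's total count and avgdl its cohort mean, multiplied by the
supervised relevance frequency

    rf = log2(2 + a / max(1, c)),

where a and c are the number of positive- and negative-class samples carrying
at least one mutation of g (presence, not summed counts — standard tf-rf
semantics; the max(1, c) guard is the usual division-by-zero protection).
Defaults k1 = 1.2, b = 0.75 are the canonical BM25 values; both are
configurable since the original parameterization is not documented. rf is a
binary contrast, so a multiclass cohort yields one weighted matrix per target
class (one-vs-rest). An all-zero count matrix (avgdl = 0) weights to zero
rather than erroring.

**3. Effectiveness ranking and union.** "Most effective genes" per class is
realized by two interchangeable rules, because the original ranking statistic
is ambiguous:

* `coef` (default): the absolute coefficient of an L2-regularized one-vs-rest
  logistic regression (C = 1, max 5,000 iterations, fixed seed) fit on the
  weighted matrix — the natural reading when the gene lists come out of a
  classification study;
* `rf_mass`: rf_g × mean positive-class bm25_tf_g, i.e. the class-mean
  weighted value — classifier-free and exactly reproducible without a solver.

Tables are sorted descending with lexicographic gene-ID tie-breaks. The
selected feature set is the union of each class's top-k genes, with per-gene
provenance recording the contributing classes.

**4. Expression side.** FPKM-style matrices are assembled from two-column
per-sample TSVs; genes missing from a file are filled with 0 (unobserved ≈
unexpressed) and the fills are logged. GMT collections are parsed with
in-set deduplication; Hallmark-style unions require an explicit symbol→ID map
rather than a hidden lookup database. No normalization is applied by default
(none is part of the method); an optional log2(1+x) transform exists at the
classifier stage. Filtering preserves the expression matrix's column order and
logs requested-but-absent genes.

**5. Evaluation.** Stratified 5-fold cross-validation (deterministic in the
seed) of an L2 logistic regression, with five metrics per fold: accuracy,
micro-averaged F1 (equal to accuracy in single-label multiclass data — the
identity is asserted by tests), micro one-vs-rest FPR (ΣFP / Σ(FP+TN); the
single reported FPR is otherwise undefined for three classes), micro-averaged
ROC-AUC (all sample×class one-vs-rest pairs flattened into one ranking
problem, scored by the Mann–Whitney rank-sum with midrank ties), and the
multiclass Matthews correlation computed directly from the confusion matrix
(reduces to the binary closed form at two classes; a degenerate denominator
returns 0 with a warning). Reports carry fold means and standard deviations
(population SD over folds) plus a configuration echo, and format tables as
percentages to two decimals with "±".

**Leakage.** Data-driven selectors (MI, mRMR, ReliefF, custom callables) are
refit inside each training fold; precomputed gene lists (GMT unions,
mutation-derived effective sets whose inputs are a separate data modality) are
constant across folds. A `leak_free=False` flag reproduces whole-dataset
selection for comparison. A spy-selector test asserts held-out samples are
never visible to fold-fit selectors.

## Baseline selectors

* **MI top-K** — plug-in mutual information on equal-frequency 5-bin
  discretized features (a k-NN estimator is optional). Constant features get
  MI 0.
* **mRMR** — greedy forward selection on 3-bin equal-frequency discretized
  features; criteria MID (relevance − mean redundancy, default) and MIQ
  (ratio). Criterion values within 1e-9 are treated as tied and resolved
  lexicographically, so floating-point summation order can never change the
  selection path.
* **ReliefF** — multiclass, Manhattan distance on internally min-max-scaled
  features (hence invariance to affine feature rescaling), n_neighbors = 10,
  all instances sampled by default (deterministic); prior-weighted miss
  contributions per other class, normalized by n_sampled × n_neighbors.

These are first-principles implementations validated against brute-force
oracles in the test suite, not attempts to bit-match any external toolkit.

## Synthetic cohort generator

The generator emulates a three-cancer-type paired cohort on a shared gene
universe. Defaults — chosen once as a desk-scale analogue of a multi-hundred-
sample tumor panel — are 3 classes × 50 samples, 2,000 genes, 30 planted genes
per class (pairwise disjoint), background mutation counts Poisson(0.1) per
gene vs Poisson(0.5) for planted genes in their own class (rate ratio 5;
Poisson rather than Bernoulli so tf > 1 occurs and BM25 saturation is
exercised), and expression exp(N(2, 1)) per gene with log-normal noise
(SD 0.5 on the log scale) times a multiplicative effect of 2 for planted
genes in-class. Mutation and expression effect sizes are independently
configurable so the transfer premise can be weakened deliberately; setting
equal rates and effect 1 produces a valid *null* cohort used as a leakage
guard. `write_vcfs` emits minimal sites-only VCFv4.2 files whose positions sit
inside a non-overlapping synthetic gene model, making
`count_mutations(write_vcfs(M)) == M` an exact identity.

What the generator does **not** emulate: mutational signatures and hotspot
structure, copy-number events, gene–gene expression covariance, batch effects,
class-imbalanced cohorts of the real data's proportions, and the real data's
dimensionality (60k genes, ~1.9k samples). Passing tests therefore show that
the machinery is correct and that the method recovers planted signal under
idealized independence assumptions — not that it will match real-cohort
metric values.

## Numerical and design notes

* All ranking surfaces break score ties lexicographically by gene ID; mRMR
  additionally applies the 1e-9 tie window described above.
* Fold assignment, LR fits and both effectiveness scores are deterministic
  given the seed; CLI runs funnel one top-level `--seed` into every stage and
  record it in the run manifest together with per-file SHA-256 checksums.
* Default problem sizes (150 × 2,000 cohort, 10 generator seeds in the
  acceptance script) keep a full pipeline run under a couple of minutes on one
  CPU while leaving planted-signal recovery comfortably away from both floor
  and ceiling.
* Gene assignment by POS containment is the simplest defensible rule; genes
  given as BED (0-based half-open) are converted to the 1-based inclusive VCF
  convention on ingest.
* `assemble_matrix` orders genes by first encounter across files, so the
  matrix is reproducible for a fixed file list; row content is independent of
  file order.

## Known limitations

* Variant consequence is ignored: a synonymous passenger counts as much as a
  truncating driver. Annotation-aware counting is out of scope.
* The rf statistic uses presence frequencies; cohorts with very different
  per-sample mutation burdens are only partially compensated by the BM25
  length normalization.
* `coef` effectiveness depends on the solver configuration; the defaults are
  recorded in outputs, but a different C or penalty changes the ranking.
* Micro-averaged FPR and F1 are dominated by large classes; macro variants are
  not implemented.
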