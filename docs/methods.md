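# Methods note

This note records the statistical model behind `microsig`, the meaning and
defaults of every parameter, the numerical choices, and the known limits of
the synthetic data generator. The package analyzes 16S OTU count tables from
a two-line chicken design (HAS/LAS antibody-selected lines, three small-
intestine tissues, replicated birds) together with host gene expression, and
searches for a minimal microbial signature of the line plus, per signature
OTU, a gene-expression pattern of its abundance class.

## 1. Synthetic data model

Real sequencing data cannot ship with the package, so every claim is
exercised on a generator whose planted structure is known exactly.

### OTU counts

For sample *i* (line *l*, tissue *t*) and OTU *j* the count is negative
binomial:

- mean `mu_ij = L_i * a_j * e_tj * f_lj`
- variance `mu + mu^2 / k` with dispersion `k = nb_dispersion`.

Components:

- `a_j`: lognormal(0, 1.5) relative abundance, normalized — a long-tailed
  rank-abundance curve as observed in gut communities.
- `L_i`: library size, `library_size_mean` times a lognormal factor with log-sd
  `library_size_sd_log` (depth varies per sample).
- `e_tj`: per-(OTU, tissue) lognormal main effect with log-sd
  `tissue_effect_sd_log` (tissues differ, but the line contrast is what is
  planted).
- `f_lj`: the planted line effect. For the `n_discriminative` discriminative
  OTUs one line (alternating per OTU) gets multiplier `fold_change`; all other
  OTUs have `f = 1`.

Discriminative OTUs draw their relative abundance from the upper half of the
abundance distribution so the planted fold change is not drowned by sampling
noise at realistic depths.

`n_exclusive_per_line` OTUs per line are structural zeros in the other line
and *sparse* in their own line (expected ~1–2 reads per positive sample):
they are detectable by presence/absence but are noisy single predictors.
This mirrors the behavior of reported line-exclusive taxa — low-abundance
organisms seen in only one line — rather than making them artificially
perfect classifiers, which would let them dominate every signature.

### Phylogeny

A random coalescent over the OTU ids: pairs of lineages are joined until one
root remains; branch lengths are `Exp(rate 10) + 1e-3` (strictly positive so
every branch contributes to UniFrac). The tree is a topology carrier for
distance computations, not an evolutionary model.

### Gene expression

`n_linked_otus` of the discriminative OTUs are linked to disjoint blocks of
`n_linked_genes_per_otu` genes. Each gene's log2 expression is a N(5, 2)
baseline plus `expr_effect_size` per ordinal abundance-class step of its OTU
(classes computed by the same Table-style rule the pipeline uses) plus
N(0, `expr_noise_sd`) noise; columns are then scaled to transcripts per
million (TPM, each sample sums to 1e6), which mildly perturbs planted shifts
exactly the way real within-sample normalization would. Linking all twenty
discriminative OTUs would make half the transcriptome line-correlated and the
per-OTU recovery question ill-posed through cross-talk, so the default is
five linked OTUs.

### Generator defaults

| parameter | default | why |
|---|---|---|
| `n_tissues`, `n_replicates` | 3, 6 | 2 lines x 3 tissues x 6 birds = 36 samples, the emulated design scale |
| `n_otus` | 450 | post-filter OTU count scale of the emulated study |
| `n_discriminative` | 20 | "top twenty" signature size of the emulated workflow |
| `n_exclusive_per_line` | 5 | a handful of line-exclusive taxa per line |
| `fold_change` | 4.0 | a strong but not trivial line effect; recovery at this value is what the acceptance run measures |
| `nb_dispersion` | 2.0 | substantial overdispersion (variance ~ mu^2/2 at large mu), typical of 16S counts |
| `library_size_mean` / `library_size_sd_log` | 50,000 / 0.3 | amplicon-scale depth with ±35% depth variation |
| `tissue_effect_sd_log` | 0.2 | mild tissue heterogeneity |
| `n_genes` | 2,000 | desk-scale transcriptome |
| `n_linked_otus` x `n_linked_genes_per_otu` | 5 x 50 | disjoint gene modules, 1/8 of genes linked |
| `expr_effect_size` | 2.0 | two log2 units per class step; recovery target of the acceptance run |
| `expr_noise_sd` | 0.25 | per-gene, per-sample log2 noise |

These values were fixed from the design being emulated and from standard
ranges for 16S/RNA-seq data before the recovery experiments were run; they
are not tuned to any test outcome.

## 2. Community statistics

- **Filtering**: OTUs with total count across all samples below `min_total`
  (default 10) are removed.
- **Alpha diversity**: observed OTU counts per sample / line / tissue.
- **Beta diversity**: weighted UniFrac (scikit-bio), optionally normalized;
  ordination by classical PCoA. Correctness is checked against an
  independent brute-force branch-enumeration oracle to 1e-10.
- **PERMANOVA** is implemented in-package: pseudo-F from among/within sums of
  squared distances, with a seeded Monte-Carlo p-value
  `(1 + #{F_perm >= F_obs}) / (1 + n_permutations)` or exact exhaustive
  enumeration of distinct label permutations for small designs. The
  in-package version exists because the interface requires a seed contract
  and an exhaustive mode; scikit-bio's `permanova` serves as an independent
  cross-check in the tests.
- **Differential abundance**: per-OTU negative binomial GLM
  (statsmodels) of counts on line with a log effective-library-size offset,
  likelihood-ratio test against the intercept-only model, chi-square(1)
  p-values; Benjamini–Hochberg FDR and Bonferroni adjustments. Effective
  library sizes are TMM-normalized (trimmed mean of M-values: 30% M-trim, 5%
  A-trim, precision weights, factors scaled to geometric mean 1). OTUs with
  all-zero counts are excluded with a warning; fits that fail (e.g. perfect
  separation for line-exclusive OTUs) yield NaN p-values and are excluded
  from the corrected families.

## 3. Stage-1 signature search

1. **Ranking.** Each OTU is scored by (a) information gain in bits about the
   line label after supervised Fayyad–Irani MDL discretization of its counts,
   and (b) its differential-abundance p-value. The two orderings are combined
   by mean rank (ties get average rank; missing p-values get the worst
   p-rank); final order breaks residual ties by OTU id for determinism.
2. **Ensemble.** Three classifiers (linear-kernel SVM, single-hidden-layer
   perceptron trained by lbfgs, CART decision tree) x two validations (one
   stratified 66/34 percent split, test side rounded down per class; and a
   stratified K-fold hold-out, K = 6, whose cell is the mean of its K runs).
   Performance is always the mean of the six cells. The split and the folds
   are built once per seed and shared by all classifiers so cells are
   comparable. Counts are standardized inside the SVM and perceptron
   pipelines (fold-local, no leakage); the tree sees raw counts.
3. **Reduction.** From all ranked OTUs, evaluate, drop the worst-ranked 20%
   (at least one), repeat down to a floor; the best set is the evaluated set
   with the highest average accuracy, the smallest on ties. The module-level
   floor default is 5; the pipeline runs with floor 20, the signature size
   target of the emulated workflow. At 36 samples the accuracy profile over
   set sizes is nearly flat, so without the size target the smallest-on-ties
   rule collapses the signature to a handful of OTUs.
4. **Filters.** Each best-set OTU is evaluated as the sole attribute with the
   same seed (same split/folds, so values are comparable); OTUs below the
   75% individual-accuracy threshold or present in only one line are removed.

Numerical choice: the perceptron's hidden layer is
`min(ceil((n_features + n_classes) / 2), 64)`. The unclipped rule gives ~226
units at 450 features, whose lbfgs fit is ~40x slower while being
statistically unidentifiable at n <= 36; the cap changes nothing measurable
at these sample sizes and keeps the iterative search tractable.

## 4. Abundance discretization

Per signature OTU, counts map to ordinal classes relative to the OTU's own
mean:

- any zero count present → *with_absent*: mean m over nonzero samples; 0 →
  Absent, count > m → High, otherwise Low;
- all samples positive → *all_present*: overall mean m; count > 1.5m → High,
  count < 0.5m → Low, the closed band [0.5m, 1.5m] → Medium.

Thresholds are mean-relative, so class assignments are invariant to
rescaling all counts. Values within 1e-9 relative distance of a cutoff are
treated as exactly on it, so one-ulp rounding after rescaling cannot flip a
boundary sample's class. OTUs whose samples all land in one class are
flagged degenerate and excluded from stage 2.

## 5. Stage-2 gene lists

Per non-degenerate signature OTU: genes are ranked by information gain about
the abundance classes (log2(TPM+1) features); the ensemble is evaluated on
nested top-k lists over a size grid (default spans 32–500); the best list
(highest mean accuracy, smallest on ties) is the OTU's gene signature.
Classes too rare to stratify (< 2 samples) are merged into their nearest
ordinal neighbor — ties toward the lower class — *for fold construction
only*; classifiers always see the original labels.

## 6. Negative controls

A control run draws a uniformly random non-identity permutation of the
sample labels, re-runs the full ensemble, and repeats (default 10
randomizations). Chance is the empirical majority-class frequency (0.5 for
balanced two-class lines, ~1/3 for balanced three-class abundance labels).
The control seed is derived from the analysis seed by a keyed hash, so
control runs can never silently reuse the analysis splits. Reported: per-run
accuracies, grand mean, chance, gap, and the Monte-Carlo standard error.

## 7. Reproducibility

Every stage seed derives from one master seed via
`blake2b(f"{master}:{stage}") mod 2^31` (`microsig._seeds.child_seed`), so a
full run is reproducible from one integer, any stage is reproducible in
isolation, and derived seeds stay in the range every library accepts. The
pipeline writes a manifest with the configuration, its hash, and all stage
seeds.

## 8. Open design decisions

- **Recall is measured on the reduction's best set, precision on the
  post-filter signature.** The filters are *designed* to shrink the
  signature (the emulated cascade narrows 20 → 11 → 9), so post-filter
  recall of all planted OTUs is structurally impossible whenever the filters
  act; the best set is the object the reduction claims is sufficient, and
  the filters are a precision device.
- **Line-exclusive OTUs are excluded from the recall denominator**: the
  both-lines filter removes them by design, so they cannot count against
  recall; they still count toward precision (they are planted).
- **K-fold construction** uses seeded stratified K-fold: with 6 replicates
  per class and K = 6, every fold holds exactly one sample per class, which
  is the property a replicate-paired fold design would give; for synthetic
  data the replicates are exchangeable, so explicit pairing adds nothing.
- **Stage 1 runs per tissue** (jejunum by default in the pipeline) or on all
  samples; the library functions take whatever table they are given.

## 9. Limitations of the generator

- No compositional coupling beyond the shared library-size factor: real
  communities have correlation structure (co-occurrence, mutual exclusion)
  that the independent-NB model lacks.
- The phylogeny is random and independent of the planted line effect, so
  UniFrac-based statistics see an unstructured (conservative) signal.
- Expression links are clean ordinal shifts on disjoint gene blocks; real
  host-microbe covariation is weaker, overlapping, and confounded with the
  line itself.
- Tissue effects are independent lognormal perturbations, not a consistent
  anatomical gradient.
- All samples are exchangeable within line x tissue; no cage, batch, or age
  structure exists.

These limits mean recovery rates measured here are upper bounds on what the
same procedures could achieve on equally sized real data.
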