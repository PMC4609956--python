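# Methods

## Detection model

Each tissue is analyzed marginally. Expression values are used exactly as
supplied — the pipeline assumes library-normalized input (the scale, log or
linear, is the caller's responsibility and is echoed in the run summary) and
performs no internal re-normalization. For each gene the model is ordinary
least squares of expression on an intercept, donor age (years), and the
active correction model's covariates: a 0/1 sex indicator (reference level
female), the top 3 genotype PCs taken from the metadata, and a subset of the
top 5 expression PCs. The age coefficient γ (expression units per year) is
tested two-sided against zero with the exact t reference distribution;
multiplicity is controlled per tissue by Benjamini–Hochberg step-up at
FDR α = 0.05. Genes with zero sample variance are reported as γ = 0, p = 1
instead of raising: bootstrap and permutation replicates can create them and
must not abort a batch run.

Expression PCs are computed on the gene-centered (not variance-scaled)
matrix via SVD; sample coordinates are the projections, components are
ordered by variance explained and sign-oriented so each component's
largest-magnitude gene loading is positive (PCA signs are otherwise
arbitrary; a fixed rule makes runs reproducible). No gene scaling is applied
because unscaled PCs are the common choice in expression-QTL-style covariate
correction and the centering alone already removes baseline differences.

### Correction models M1–M9

M1 fits age alone; M2 adds sex and the genotype PCs; M3–M7 additionally
correct the expression PCs whose |Pearson r| with age falls below 0.1, 0.2,
0.3, 0.4, 0.5; M9 (default) corrects the PCs whose age-correlation p-value
exceeds 0.05; M8 searches all subsets of the top k PCs exhaustively and
keeps the subset maximizing the BH-significant count, breaking ties toward
the smaller subset and then lexicographically. The search is refused beyond
256 subsets (k > 8) — it is meant for the top-5 default, not as a general
combinatorial optimizer. M8 deliberately over-calls (correcting an
age-aligned PC can shrink per-gene residuals while leaving a spurious age
signal), which is why it serves as the conservative *null* model in the
permutation analysis: it upper-bounds the false-positive count.

### Low-expression filter

Called genes are scored by the mean of their expression over the top
⌈0.25·n⌉ samples (each gene's own top samples); genes rank by score
descending with ties broken by gene id ascending, and the bottom
⌊0.20·m⌋ of the m called genes are dropped. Ceiling/floor and the id
tie-break make the filter deterministic and order-free.

### Bootstrap consensus and permutation null

The bootstrap draws samples with replacement, reruns the full detection
(PCs recomputed inside each resample — they are sample statistics, and
reusing full-sample PCs would leak information), and counts per-gene
support; within a resample "significant" means BH FDR < α in that resample,
mirroring the full-sample rule. The consensus signature is the genes with
support ≥ 50 of 100 runs (a strict > variant is available; the two
conventions differ only for genes sitting exactly at the threshold) that are
also BH-significant on the full sample. The low-expression filter is
evaluated once on the full-sample call and reported per gene rather than
intersected into the consensus: its score ranking is a population quantity,
and letting it fluctuate per resample only erodes support for genes near the
score boundary. Callers wanting the filtered signature intersect with the
`passed_low_expression_filter` flag (or pass `apply_filter=True`).
Degenerate resamples (too few distinct samples to fit the design, or
constant ages) are redrawn and logged.

The permutation null shuffles ages across a tissue's samples — sex and
genotype PCs stay attached to their samples, so only the age–expression link
is broken — and reruns regression + BH (+ filter) per permutation under M8
by default, without bootstrapping (1,000 bootstrap-inside-permutation runs
would be quadratic in cost and the count statistic does not need it). A
tissue whose observed count is matched or exceeded more than 5 times in
1,000 permutations is flagged as unreliable.

## Co-aging

Apparent age is the sample coordinate on PC1 of the aging-gene submatrix,
sign-oriented so that Spearman(PC1, age) ≥ 0. The co-aging coefficient of
two tissues is the Spearman correlation of apparent ages across donors
profiled in both (pairs sharing fewer than 3 donors are reported missing,
not zero). Rank deviation restricts to donors present in *all* tissues,
recomputes integer ranks within that overlap (ties broken by donor id), and
uses the root-mean-square form d = sqrt((1/n)·Σ(r_i − r)²) so values are
comparable across tissue-set sizes; the unnormalized Euclidean distance is
available as an option. Outlier p-values are the upper tail of a normal with
moments estimated from the observed d distribution — a pragmatic choice, as
d is a bounded rank statistic and the normal fit is only used to flag the
extreme tail. The young/old partition is Ward-linkage agglomerative
clustering (Euclidean distance) cut at two clusters, the lower-mean-age
cluster labeled young, with a two-sided two-sample t-test on ages.

## Age prediction

The elastic net predicts chronological age from all genes (optionally only
the aging signature). Samples are split into 10 near-equal random folds;
each fold is predicted by a model trained on the other nine, with penalty
strength and L1/L2 mixing (grid 0.1/0.5/0.9, 10-point penalty path) chosen
by 5-fold cross-validation inside the training portion — nested CV avoids
optimistically biased hyperparameters. Features are standardized on the
training fold only. The whole split is repeated (default 100; the test
suite and acceptance script use 5–10 repeats, which empirically already
stabilizes the mean) and the per-sample mean across repeats is the predicted
age; RMSE is reported in years. Internally genes and samples are reordered
canonically by id so predictions do not depend on input ordering.

## Over-representation

`fisher_overlap` is the inclusive upper-tail hypergeometric probability
P(X ≥ overlap), equivalent to the one-tail Fisher exact test on the 2×2
table; every application is over-representation (upper tail). The disease
scan tests up- and down-signatures separately against each set, within a
per-tissue universe equal to the genes tested in that tissue (a defensible
conditional background; a fixed global universe can be supplied instead),
selects the top-10 sets per tissue/direction, and normalizes −log10 p by the
display maximum to a [0,1] score. Raw p-values are reported with a BH
column alongside; the scan itself applies no correction, since its role is
ranking hypotheses for display. Cross-species overlap calls aging genes at
a raw per-gene p < 0.001 (not FDR) inside the homolog universe; cross-study
overlap intersects both signatures with a shared universe first.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: integer ages
uniform on 20–70; a latent per-tissue biological age b = age +
deviation_sd·z with z multivariate normal under a configurable tissue
correlation matrix (unit diagonal, PSD-checked); log-normal baselines
(log-mean 1, log-sd 1) so the low-expression filter has a real gradient;
planted signed age effects γ (normal with sd 0.05/yr, or fixed magnitude
with random sign) acting on b; sex effects (sd 0.3), genotype-PC effects
(sd 0.1), uniform batch assignment with per-gene batch loadings (sd 0.5);
i.i.d. Gaussian noise (sd 1). Expression is left unclipped/real-valued
(log-scale semantics) so the linear-model assumptions hold exactly. Each
tissue samples its donors uniformly without replacement, creating realistic
partial donor overlap. RNG sub-streams are keyed by tissue name, so
reordering the tissue list does not change any tissue's data.

The genotype-effect default deserves a note: population-structure PCs
explain at most a few percent of bulk expression variance in real cohorts,
and the default (sd 0.1, ≈ 3% of variance) reflects that. Much larger
values push the genotype component into the top expression PCs, where
including both the genotype covariates and those PCs lets a covariate
combination reconstruct the age direction that eigenvalue mixing leaks into
them — a double-correction pathology that inflates the age standard error
severalfold. That regime is a stress test, not a realistic default.

What the generator does *not* emulate: count-level (negative-binomial)
sampling, mean–variance coupling, gene–gene correlation beyond the planted
factors, missing values, or longitudinal structure. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
linear-Gaussian model, not robustness to every property of real RNA-seq.

## Validation conditions and problem sizes

The shipped checks use sizes chosen to exercise each property at desk
scale: null calibration on 200 cohorts of 500 genes × 80 samples (mean
discovery count < 1 at FDR 0.05; pooled p-values within 1% of uniform in
CDF — the small residual deviation comes from correcting data-derived PC
covariates); parameter recovery on 2,000 genes × 120 samples with 10%
planted effects of 0.05 units/yr against unit noise (per-gene t ≈ 8), 20
seeds, with deviation_sd = 0 since the planted effect is defined per year of
chronological age; co-aging recovery with three tissues at latent pair
correlations (0.8, 0.5, 0.2), 150 donors, deviation_sd = 10, judged against
the oracle Spearman of the latent biological ages; prediction on a
200-sample cohort whose 400 genes all carry 0.1 units/yr signal plus batch
structure of comparable magnitude (sd 1.5) — the regime where the
supervised predictor separates from the unsupervised PC1 projection —
at 10 repeats of 10-fold CV.

## Known limitations

* The per-gene model is homoscedastic OLS; no robust or mixed-effects
  variants, no surrogate-variable methods beyond PC regression.
* The normal fit for rank-deviation outliers is a convenience; with few
  overlapping donors its tail probabilities are rough.
* M8's exhaustive search is exponential in the PC count and capped at 8.
* The disease scan reports raw p-values by design; treat them as a ranking,
  not calibrated significance, unless the BH column is used.
* Genotype PCs are consumed from metadata, never computed from genotypes.
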