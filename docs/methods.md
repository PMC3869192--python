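# Methods

## Problem and overall design

`gutage` asks whether the functional content of a human-gut metagenome
carries a signal of its host's age, and at which point in the lifespan that
signal is strongest. The data are samples × features tables of non-negative
abundances, where a feature is a protein family (Pfam), KEGG pathway, KEGG
ortholog or GO term and each entry counts the *distinct* non-redundant
proteins of a sample assigned to that feature — a measure of within-family
protein diversity, not of expression.

Because "young" and "old" have no natural boundary, the cohort is
dichotomized at an integer age cutoff c (young ⇔ age ≤ c) and the whole
classification experiment is repeated as c sweeps across the cohort's age
range one year at a time. For each cutoff, random subsets of the cohort are
drawn and evaluated by leave-one-out cross-validation in which feature
selection is re-run *inside every fold* on the training samples only;
a linear soft-margin SVM is fit on the selected features, and the left-out
sample's decision score is recorded. Per-run AUC is computed by pooling the
left-out decision scores of that run (the protocol does not prescribe
pooling versus per-fold averaging; pooling is the package's choice because a
single left-out sample has no ROC of its own); the mean, a t-based 95%
confidence interval across runs, mean accuracy, and per-feature selection
rates are then reported per cutoff.

## Feature selection

**TF-iDF.** For sample j and feature i with count n_ij,
tfidf_ij = (n_ij / Σ_k n_kj) · log(|D| / m_i), with |D| the number of
samples and m_i the number of samples containing feature i. The logarithm is
natural by default; the base uniformly rescales all weights and cannot
reorder features, so it is exposed only as a convenience parameter. TF-iDF
scores (sample, feature) cells, but selection needs one score per feature:
the package aggregates by the **maximum** weight over training samples,
which matches the selection target — features taking a large share of a few
samples' assignments while rare across samples ("accessory" features). Sum
aggregation is available by configuration. Class labels are never consulted.

**mRMR.** Counts are first discretized feature-wise to {−1, 0, +1} at
mean ± t·σ (sample standard deviation, default threshold t = 1; constant
columns map to 0). Greedy forward selection then maximizes plug-in mutual
information (base 2) with the young/old label minus the mean mutual
information with already-selected features — the difference ("MID")
combination, matching the reference implementation's default; the quotient
form is available by configuration. Ties break lexicographically on feature
identifier, which makes rankings fully deterministic. The per-step relevance
D(S, c) and redundancy R(S) (diagonal self-information included) are
recorded in the ranking's trace.

One consequence of the mean ± σ discretization worth knowing: a presence/
absence feature occurring in about half the samples discretizes to all
zeros (neither tail exceeds one standard deviation), so mRMR is most
sensitive to presence differentials away from 50% prevalence — which the
planted 55%-vs-11% pattern satisfies.

**Grubbs-weighted selection.** A control for TF-iDF's preference for rare
patterns. Each feature's abundance vector across the training samples is
screened with Grubbs' two-sided single-outlier test (G = max |v − mean| / sd,
sample sd; critical value from the t-distribution formula at α = 0.05,
non-iterative). Every flagged training sample s, with flagging feature set
P_s, is classified by a linear SVM trained on the remaining training samples
restricted to P_s; each feature of P_s earns weight 1 when the prediction is
correct, and features are ranked by accumulated weight. Features never
flagged keep weight 0 and are not ranked; if nothing is flagged the ranking
is empty and the fold is skipped with a warning.

## Classification

A soft-margin linear SVM (sklearn's libsvm binding) with C = 1 by default.
No feature scaling is applied by default — the counts enter as-is; per-fold
z-scoring with training-fold statistics is available behind a flag. The
decision orientation is fixed (positive score = old) so pooled scores give a
well-defined ROC. Before fitting, identical (row, label) pairs are merged
into one sample weighted by its multiplicity; the hinge terms add, so the
optimization problem is unchanged, while the solver avoids cycling on the
duplicate all-zero rows that sparse feature selection routinely produces.
Label symmetry and sample-order invariance consequently hold to the solver's
convergence tolerance (~1e-3 on decision values), not to machine precision.

## Evaluation statistics

AUC is computed by the Mann–Whitney rank formula with ties half-credited —
exactly the probability that a random old sample outscores a random young
one. Confidence intervals across the n_runs = 20 runs use the t distribution
(mean ± t₀.₉₇₅,₁₉ · sd/√20). Subsets are simple uniform draws without
replacement (no age or country stratification); a draw missing one class is
redrawn. All randomness flows from one master seed: each cutoff derives a
child seed from (seed, cutoff), so adding or removing cutoffs leaves the
other rows bit-identical.

The chance baseline is computed by `permutation_null_experiment`, which
shuffles the hosts' ages across samples with a fresh derived seed in every
run before drawing that run's subset. Averaging over permutations matters:
any single permutation retains chance association between the shuffled
labels and particular features, which varies with the cutoff and can move
one fixed-permutation mean AUC a few points off 0.5; the per-run
permutation protocol estimates the actual null distribution.

## Ordination

Transformation-based PCA: each sample row is Hellinger-transformed
(square root of within-sample relative abundance, giving unit-norm rows),
the matrix is column-centered, and an SVD provides scores and
explained-variance fractions. Component signs are fixed by making each
component's largest-magnitude feature loading positive, so ordinations are
reproducible. When ordinating on a selected feature subset, relative
abundances are recomputed *within* the subset, keeping the transform a valid
composition on the reduced table; samples with zero coverage on the subset
lie outside the transform's domain and must be dropped by the caller.

## Synthetic cohorts

The generator emulates the structure the analysis assumes in real functional
tables:

| parameter | default | rationale |
|---|---|---|
| n_samples | 120 | the large reference cohort's scale (124 hosts) |
| n_features | 500 | desk-scale stand-in for thousands of Pfams |
| background_presence | 0.5 | ~half the cells of real tables are empty |
| frac_sample_unique | 0.15 | ~15% of Pfams occur in exactly one metagenome |
| count_scale / dispersion | 20 / 2 | gamma-Poisson (negative-binomial-like) over-dispersion typical of metagenome counts |
| age_distribution | uniform 22–87 | the age-balanced multi-study design; `qin_like` reproduces the 85%-over-40 skew |
| countries | Spain/Denmark 50:50 | two-country batch structure |
| country_batch_multiplier | 3× on a random 10% feature subset | nationality as a visible, age-orthogonal source of variation |

Age signal is planted in two regimes. `prevalence_shift` features are
present in a different fraction of the young than of the old (default 55%
vs 11% at cutoff 40 — the strongest presence differential reported for a
vitamin-B12-synthesis family); this targets the mutual-information
selector. `accessory_burst` features are present in a small fraction of the
young only (default 25% vs 2%) at 30× abundance — high within-sample share,
rare across samples — the regime TF-iDF selects. Burst carriers draw their
counts at low over-dispersion (`burst_dispersion`, default 50): the burst is
defined by its share of the sample, not by carrier-to-carrier spread, so a
burst feature's largest carrier is not an *internal* outlier of its own
abundance vector.

### The outlier-structure control cohort

`broad_accessory_effects` spreads burst-type signal over 90% of the young
class (vs 10% of the old). With ~10+ carriers in any 40-sample training
set, the maximum standardized deviation of such a feature's abundance
vector stays below the Grubbs critical value — sparser signal (≤3 carriers
in a training set) would itself be single-sample outlier structure. On this
cohort the Grubbs-weighted selector can only rank noise features, while
TF-iDF still finds the high-share, across-sample-rare signal.

Two design details make this control statistically meaningful. First,
because every feature flags at most one training sample, per-fold Grubbs
weights are 0/1 and "top 10 by weight" degenerates to the lexicographic
tie-break over the weight-1 set — the selection concentrates on a nearly
fixed feature subset across folds and runs. Second, any fixed feature
subset of a finite cohort carries chance class correlations of order
1/√n that persist between training folds and left-out samples of the same
cohort, biasing a concentrated selector's leave-one-out AUC away from 0.5
(measured at +0.06 ± 0.17 per run for arbitrary fixed noise features at
n = 120). The control cohort therefore uses n = 240 samples, which halves
the chance-correlation scale while keeping the evaluation protocol (20 runs
of 40-sample subsets, top-10 selection) identical.

Two generator properties are exact by construction: cohorts are bit-
reproducible from the seed, and exactly round(frac_sample_unique ×
n_features) features occur in exactly one sample (that many features are
designated sample-unique; any other feature whose drawn presence lands on a
single sample receives a second occurrence in a random other sample).

What the generator does **not** emulate: phylogenetic correlation between
features (real protein families co-occur along genomes and taxa), read-depth
variation between samples, age as a continuous gradient (signal switches at
the planted cutoff rather than drifting), and annotation noise. Passing
recovery tests therefore shows the pipeline finds the planted statistical
patterns at realistic sparsity and dispersion — not that equally strong
patterns exist in any real cohort.

## Problem sizes and numerical choices

Pipeline-level checks run at 120 samples × 500 features with 20 runs of
40-sample subsets and top-10 selection — the age-balanced study's subset
configuration applied to the generator's default cohort; the sweep covers
cutoffs 34–46 at 1–3-year spacing around the planted cutoff. Oracle checks
use 20×30 to 40×8 matrices where exhaustive evaluation is cheap.
Degenerate inputs are defined rather than left to chance: sd = 0 gives
G = 0 (no outlier) in Grubbs' test and an all-zero discretized column in
mRMR; features present everywhere or nowhere get TF-iDF weight 0; folds
whose training set loses a class, or whose selector returns no features, are
skipped with a logged warning and excluded from the accuracy denominator.
All ranking ties resolve lexicographically on feature identifier.

## Known limitations

* The GO-transfer threshold is applied as best-hit e-value ≤ 1e-5; the
  parser trusts the upstream search tool for Pfam gathering-threshold
  filtering (GA values live in the model files, not the hit tables).
* mRMR relevance is estimated by plug-in MI on 39-sample folds; with
  thousands of features the selection is noisy, which is visible in its
  wider confidence intervals.
* Grubbs-weighted selection is quadratic-ish in practice (one SVM per
  flagged training sample per fold) and is the slowest selector by far.
* AUC pooling across folds assumes decision scores are comparable between
  folds; per-fold selection makes this only approximately true.
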