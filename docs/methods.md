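# Methods

`prognosig` re-implements, at desk scale, a tissue-to-saliva biomarker
pipeline for oral squamous cell carcinoma (OSCC) prognosis: differential
discovery proteomics of microdissected tumor regions, targeted saliva
quantification by selected reaction monitoring (SRM), semi-quantitative
immunohistochemistry (IHC) scoring, and an exhaustive machine-learning
search for peptide/protein signatures of lymph-node status. This note
records the models, the defaults and why they were chosen, what the
synthetic data does and does not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer.

## Tissue discovery model

Input is a proteins × samples matrix of log2 label-free quantification
(LFQ) intensities from two regions per patient: the invasive tumor front
(ITF, the ~1 mm zone at the invading edge) and the inner tumor, in either
the neoplastic-island or the stromal compartment.

**Valid-value filter.** A protein is retained when it has at least
`min_valid` observed values in *at least one* region (default 10 for
island comparisons, 8 for stroma). Region-exclusive proteins therefore
survive and feed the presence partition (`presence_partition`), which
splits retained proteins into ITF-only / inner-only / common sets.

**Imputation.** Missing LFQ values are assumed left-censored (below the
detection limit). Each sample column's missing entries are drawn from
`Normal(μ_col − shift·σ_col, (width·σ_col)²)` with `shift = 1.8`,
`width = 0.3` — the common proteomics convention of a narrowed,
down-shifted Gaussian near the noise floor. Imputation is per sample
column; observed values are never modified, and a column needs at least
two observed values to estimate its moments (otherwise the imputation
aborts naming the column).

**Differential testing.** Student's t test per protein, two modes:
classic pooled-variance unpaired (used for island comparisons) and
paired by patient (stromal comparisons, where both regions of a patient
were microdissected from one section). Both modes are exposed because
the island-level pairing is a genuinely open choice. The effect size
reported is `mean(ITF) − mean(inner)` on the log2 scale. Zero-variance,
zero-difference rows are reported as t = 0, p = 1 rather than NaN.

**Clustering and QC.** Heat-map dendrograms z-score each protein row and
agglomerate samples (or proteins) on Euclidean distance with complete or
average linkage; ties merge lowest-index-first and leaf order is the
standard left-subtree-first traversal. Sample-level QC uses
pairwise-complete Pearson correlation with a minimum overlap of 3
observed proteins per pair.

**Prioritization.** Candidates must pass the differential gate
(t-test p < 0.05) and, for at least one clinical covariate, a linear
association gate: OLS p < 0.05, |r| strictly greater than 0.7, and
r² > 0.4. Categorical covariates are numerically encoded (binary 0/1,
ordered categories as integer ranks) so each covariate yields a single
correlation coefficient. External evidence (staining patterns,
literature novelty) enters as an allow-list intersection rather than a
computed gate.

## SRM quantification model

Each monitored peptide is measured as 3 fragment transitions for the
endogenous (light) form and a spiked stable-isotope-labelled (heavy)
standard, in 3 technical replicates. Per replicate the light/heavy
ratio is `Σ light areas / Σ heavy areas`; the heavy spike is constant,
so L/H is relative endogenous abundance. `rdotp` — the normalized dot
product of the light and heavy transition vectors — is the QC statistic
for fragmentation-pattern identity (1 iff proportional); replicates can
be gated on a minimum rdotp before aggregation.

Replicates are aggregated by the arithmetic mean of their ratios (a
convention; the mean is the least-surprising choice where lab protocols
differ), with the coefficient of variation reported and flagged above
0.2 but never silently dropped. Protein-level abundance is the unweighted
mean of the protein's peptide ratios within each patient (a "best
peptide by replicate CV" mode exists behind a flag).

Group comparison (N+ vs N0) uses the two-sided Mann–Whitney U test on
*untransformed* ratios — exact null distribution when both groups have
n ≤ 8 without ties, otherwise the normal approximation with tie and
continuity corrections — with Benjamini–Hochberg adjustment. The BH
family is all monitored peptides (14) for the peptide table and all
proteins (7) for the protein table, as two separate families; treating
the two levels as separate families is a package decision (practice in
the field varies). The reported effect is
`log2(median N+ / median N0)`.

## IHC scoring model

Staining is rated per region on two ordinal scales — intensity 0–3
(negative/weak/moderate/strong) and stained-cell percentage 0–3 (0%,
≤25%, 26–50%, >50%) — whose sum is the combined score 0–6. The bin
boundaries are a configurable convention (`INTENSITY_BINS`,
`PERCENTAGE_BINS`); several close variants circulate in the field.
`ITF − inner` classifies each case: negative → lower in ITF, positive →
higher, zero → equal; a case with exactly one unscored region is called
equal (it cannot be compared), and a case with both regions missing is
an error. Inter-rater agreement uses Fleiss' multi-rater kappa on the
categorical calls made *before* consensus adjudication; the consensus
value is expected in the input. Clinical association uses Pearson
chi-square crosstabs without continuity correction.

## Signature search

The machine-learning stage estimates the prognostic power of every
peptide/protein panel on a 14 N0 / 26 N+ cohort:

1. **Split** — stratified 80/20 holdout by per-class rounding
   (`round(0.2·14) = 3` N0 and `round(0.2·26) = 5` N+ in the test set).
2. **Filter** — per-feature Mann–Whitney p < 0.10 on the *training set
   only*.
3. **Enumerate** — all `2^N − 1` non-empty subsets of the retained
   features, ordered by size then lexicographically, refused above
   N = 20. (With 10 retained peptides this is 1023 panels; a count of
   1024 arises only if the empty set or an all-features baseline is
   also counted.)
4. **Cross-validate** — per signature, repeated stratified k-fold CV
   (default 100 repetitions × 10 folds). Each repetition draws a fresh
   fold assignment (seed `base_seed + repetition`); metrics are computed
   per repetition on the pooled out-of-fold scores, which is stabler than
   per-fold averaging when a fold holds only ~4 patients. The result
   stores the full 100-value distribution per metric (accuracy, ROC AUC,
   F1, sensitivity, specificity, precision; positive class N+,
   probability threshold 0.5).
5. **Balance (optional)** — SMOTE on each training fold only: a synthetic
   minority sample is `x + u·(neighbor − x)` with `u ~ Uniform(0,1)` and
   the neighbor one of the k = 5 nearest minority samples (Euclidean on
   features standardized by the minority fold's mean/sd, since L/H ratios
   span scales; a raw-space option exists). Classes are exactly balanced
   (14/26 → 26/26 adds 12 synthetic points) and synthetic points never
   enter an evaluation fold — the audit trail in `repeated_cv` makes
   this assertable.
6. **Select** — signatures below a mean-accuracy floor are dropped; the
   rest rank by mean AUC, ties broken toward the smaller panel. The final
   panel is refit once on the full training set and validated on the
   untouched 20% holdout.

Classifiers satisfy a small contract (`factory(seed)` → sklearn-style
estimator); the registry carries the seven-algorithm sweep set (linear
SVM, RBF SVM, decision tree, logistic regression, random forest,
perceptron, naive Bayes). The default evaluation classifier is a
500-tree random forest with √p features per split. For *exhaustive*
sweeps (dozens of signatures × hundreds of fits each) the package uses
the Gaussian naive-Bayes contract, whose closed-form fit makes the full
enumeration tractable on one CPU; the selected signature is then
confirmed with the random forest. ROC AUC is computed from midranks and
equals the Mann–Whitney U scaled by `1/(n₊·n₋)` — an identity the test
suite checks against both modules.

Every stochastic step derives its seed from `CVConfig.base_seed` by
fixed documented strides (fold shuffles `base_seed + rep`; SMOTE
`base_seed + 100003·rep + 1009·fold`; classifiers
`base_seed + 7919·rep + 1009·fold`; all mod 2³¹), so any run replays
bit-identically.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the analyses
assume, with every distributional choice being a package decision:

* **Tissue** (`gen_tissue_cohort`) — 20 patients × two regions;
  per-protein baselines `N(26, 2²)` on the log2 LFQ scale; a planted
  fraction of proteins shifted in the ITF; a patient×protein effect
  shared by both regions (`sd_patient`, default 0.5) that makes pairs
  genuinely correlated (so the paired test is more powerful than the
  unpaired, as in real paired designs); within-sample noise
  (`sd_within`, default 0.7); and logistic intensity-dependent dropout
  centred on the baseline mean so the average missing rate tracks
  `missing_rate_base` while low-abundance proteins drop out more.
* **Saliva SRM** (`gen_srm_cohort`) — 14 N0 / 26 N+ patients, the 14
  canonical peptides (3 transitions × light/heavy × 3 replicates =
  10,080 records). Heavy areas are group-independent; light areas equal
  heavy × the patient's true ratio, so at zero technical noise the
  sum-ratio recovers truth exactly. True log2 ratios are peptide
  baseline + group effect + between-patient biology
  (`sd_biological_log2`, default 0.5 — added because without it the
  group test has degenerate power); technical noise is log-normal
  multiplicative with log2 sd `log2(1 + noise_cv)`, which keeps areas
  positive and matches MS intensity behavior.
* **IHC** (`gen_ihc_cohort`) — consensus combined scores consistent with
  a latent lower-in-ITF call (probability `p_lower_itf`); raters
  reproduce consensus categories with probability `rater_agreement`
  (default 0.85, which lands Fleiss kappa near 0.7) and otherwise shift
  one category; the adverse outcome is Bernoulli with log-odds shifted
  by `log(odds ratio)` for lower-in-ITF cases.

Not emulated: chromatographic peak shapes, retention-time drift beyond a
scalar per-replicate value, batch effects, correlated protein modules,
real clinical-covariate structure, or the actual spectra behind LFQ.
Passing tests therefore demonstrate that the *procedures* are correct
and well-calibrated (uniform null p-values, planted effects recovered,
no train/test leakage) — not that any particular clinical cohort's
effect sizes would be reproduced, which depends on the biology and the
instruments, not on this code.

## Numerical choices and degenerate inputs

* Pooled-variance ("Student's") t, not Welch; paired rows with zero
  difference and zero variance → t = 0, p = 1.
* Mann–Whitney switches exact → corrected-normal at n > 8 or any tie;
  the two branches agree within 0.02 at n = m = 8.
* BH adjustment is the standard step-up with cumulative minimum,
  clipped at 1; order-invariant.
* Constant rows abort z-scoring (named protein); constant covariates
  abort regression; all-zero transition vectors abort rdotp; zero heavy
  sums abort the ratio; zero contingency marginals abort the chi-square.
* SMOTE reduces k with a warning when the minority has ≤ k members and
  refuses a singleton minority; stratified CV reduces the fold count
  with a warning when the smallest class is smaller than the fold count.
* Holdout splits guarantee both classes on both sides (at least one and
  at most n−1 per class in the test set).

## Problem sizes used by the acceptance script

`scripts/acceptance.py` runs the full chain at the study's cohort sizes
(800 tissue proteins across 20 patients; the 40-patient saliva cohort;
125 IHC cases). The exhaustive signature sweep uses the naive-Bayes
contract at 25 repetitions × 10 folds; the selected signature is then
confirmed with the 500-tree random forest at the same schedule
(imbalanced and SMOTE-balanced) and validated on the 8-patient holdout.
On real export tables the same functions run unchanged at 100
repetitions.

## Known limitations

* The replicate-aggregation rule (mean of per-replicate ratios) and the
  protein roll-up (mean over peptides) are conventions; results at the
  protein level shift slightly under the best-peptide mode.
* Fleiss' kappa treats the three-way region call as nominal; ordinal
  weighting would credit near-misses.
* The exhaustive search is bounded at 20 features by design; larger
  feature spaces need the univariate filter (or an external wrapper) to
  come down first.
* Signatures whose CV AUCs differ by less than fold-assignment noise are
  statistical near-ties; the ranking among them is not stable across
  seeds, which is why the selection rule prefers smaller panels at equal
  AUC and why top-ranked panels should be confirmed on a holdout.
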