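# Methods

`tnegsig` implements a prognostic gene-signature discovery and
evaluation pipeline for node-negative, adjuvant-naive hormone
receptor-negative (HRneg) and triple-negative (Tneg) breast cancer
cohorts profiled on expression microarrays, together with a synthetic
cohort generator that makes every stage testable without access to the
original repositories.

## The model

The clinical outcome throughout is distant metastasis-free survival
(DMFS): time from diagnosis to distant relapse, administratively
censored. All survival modelling is proportional hazards,

    h(t | x) = h0(t) · exp(β·x),

with log2-scale expression covariates. Single-gene screening uses the
Wald P of the univariate Cox coefficient; group comparisons use the
unweighted log-rank test and the Cox hazard ratio of a high/low group
indicator with a normal-approximation 95% CI on the log-hazard scale.
Ties are handled with the Efron approximation (the Breslow variant is
available in the batched solver; the two coincide exactly on untied
data). These are documented choices — the analysis protocol being
reproduced does not state its tie or CI conventions.

## Discovery chain

Candidates are selected on a discovery subset (two of the three
training sources, n=135 in the emulated layout) and confirmed on the
held-out third source (n=64); the same chain is run on all HRneg
samples and again on the Tneg subset, and the final signature is the
union of the two candidate lists.

1. **PAM screen.** Nearest-shrunken-centroid scores
   `d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s_0))` with
   `m_k = sqrt(1/n_k − 1/n)`, pooled within-class `s_i` and `s_0` the
   median of the `s_i`, computed per data source against a binary
   distant-metastasis event label. The soft threshold is chosen so that
   about `top_k` (default 300) features survive per source; features
   selected in every source with the same score sign are kept. The
   event-vs-event-free labelling is itself a documented decision (the
   protocol never states the PAM classes); a 5-year landmark labelling
   would be the natural alternative.
2. **Monte-Carlo cross-validation Cox screen.** The discovery data are
   Z-transformed within source (sample SD, n−1), concatenated, and
   passed through a minimum-variation filter (feature kept iff >10% of
   samples deviate from the feature mean by strictly more than 1.0 log2
   units). 100 random learning/test splits are drawn with event counts
   balanced to within one (splits depend only on sample ids, so sample
   order is irrelevant); each half gets a univariate Cox fit per
   feature. Selection requires the arithmetic mean Wald P over all 200
   fits to be below 0.01 *and* coefficient-sign agreement between the
   halves in more than 80% of iterations.
3. **Cox consistency.** The union of the two screens' candidates is
   fitted jointly (all candidates as covariates, no clinical terms);
   features whose univariate and multivariate coefficient signs agree
   are kept. Collinear or separated designs fall back to a lightly
   ridge-penalised joint fit (penalty 1e-4).
4. **Holdout confirmation.** Candidates are confirmed iff the
   univariate coefficient sign on the mean-centred holdout source
   matches the discovery sign.

## Composite index

A signature is a set of gene symbols with hazard directions: `P` for
hazard-increasing, `N` for protective. The per-sample index is the
sign-corrected unweighted mean

    score = ( Σ_{i∈P} x_i − Σ_{j∈N} x_j ) / n,

where `n` counts only the signature genes present in the cohort
(absent genes reduce `n`; no re-weighting). Equal weighting is
deliberate — the construction being reproduced explicitly refuses
per-gene coefficients.

Dichotomisation uses the `index ≥ cut` rule (the boundary sample goes
to the high-risk group); with distinct values and a requested
percentile `pct` the low group holds exactly `ceil(n·pct/100)`
samples, so the upper-third-quartile cut places 75% of patients in the
good-prognosis group. Cut-point optimisation evaluates the log-rank P
at every distinct index value whose implied split lies within the
20th–80th percentile band (guarding against extreme group sizes) and
returns the arg-min, breaking ties toward the cut closest to the 75th
percentile. No multiplicity correction is applied inside the search;
the optimised P is labelled exploratory in all outputs.

Stepwise prioritisation greedily adds (or removes) one gene at a time,
scoring each candidate index by the Wald P of a continuous univariate
Cox fit. P rather than the raw coefficient is the default score
because coefficients are not comparable across index sizes; a
coefficient mode is available.

## Multi-source merging

Two batch-merge strategies are provided, both pure per-source
translations (so within-source variances, correlations and pairwise
distances are preserved exactly):

* `center` — per-source mean-centring of the intersected features;
* `dwd_lite` — each non-reference batch is translated so its centroid
  coincides with the reference centroid; a margin-weighted
  linear-discriminant direction (inverse-spread-weighted mean
  difference, as in shrunken-centroid scoring) is used to verify that
  no projected separation remains (< 1e-6).

`dwd_lite` is a deliberate simplification of distance-weighted
discrimination: in this pipeline DWD's only role is to remove
inter-batch location shifts before index computation, and a pure
translation achieves that while provably leaving every within-source
statistic untouched. The full second-order-cone formulation is out of
scope and could be plugged in behind the same interface.

HER2 status is called from per-source mean-centred log2 ERBB2
transcript levels: positive iff strictly above 0. The 0 threshold is a
design choice (the protocol names the variable but not the cut) and is
configurable. The triple-negative flag is ER-negative AND
PR-not-positive AND HER2-negative; a missing PR annotation does not
block the call.

## Synthetic cohort generator

The generator emulates the pooled training cohort's structure, not
microarray physics: it starts at normalised log2 expression.

* Three sources of 69/66/64 samples (total 199); additive
  per-(source, gene) batch offsets, SD 0.5 log2 units. The 0.5 is a
  free choice — no quantitative inter-source batch magnitude is
  published for these cohorts — selected so that batch shifts are
  comparable to one biological SD and clearly visible to the merging
  stages.
* 14 prognostic genes by default, 12 protective / 2 hazard-increasing,
  |β| = 0.2 per 1 SD of expression. Prognostic genes share a latent
  per-sample risk factor (loading 0.3), so the composite index carries
  more signal than any single gene; with these defaults the marginal
  per-gene Cox coefficients land in the 0.2–0.4 range, matching the
  published per-gene coefficients (0.17–0.59).
* Survival: exponential baseline λ = 0.0045 events/month modulated by
  exp(β·x) on the biological (pre-batch) signal; administrative
  censoring Uniform(60, 90) months. These values were calibrated
  numerically so that about one third of cases have an observed event
  and ~85% of events fall within 60 months of diagnosis, the tempo
  characteristic of conservatively managed early-stage Tneg disease.
  `calibrate_baseline_hazard` re-solves λ for other effect
  configurations, since strong planted effects otherwise inflate the
  event fraction through the composite exp(β·x) frailty.
* An ERBB2-like gene is a two-component mixture (HER2-positive mode
  elevated by 3 log2 units, positive fraction 45/199) and the HER2
  label is *not* emitted — it must be re-derived downstream, so the
  assignment operation is honestly exercised.

What the generator does not emulate: probe-level noise models,
platform-specific dynamic range, missing values, correlated null genes
(nulls are independent), non-proportional hazards, or informative
censoring. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean PH world, not robustness to every
real-data pathology.

## Numerical choices

* Batched univariate Cox: Newton–Raphson from β=0, step clipped to
  |Δβ| ≤ 2, convergence at |gradient| < 1e-8 or 100 iterations;
  monotone-likelihood features are capped at |β| = 15 and flagged
  non-converged; constant features are flagged with coefficient 0 and
  P = 1. Verified against lifelines to ~1e-5 including tied data.
* Zero-variance features in the Z-transform are left centred at zero
  and recorded, never divided.
* The variance filter uses a strict inequality on the deviation
  ("greater than twofold") and a non-strict one on the sample fraction.
* Stepwise and cut-point ties break deterministically (lexicographic /
  toward the 75th percentile) so runs are reproducible.
* The pipeline derives per-stage RNG seeds by stable hashing of the
  stage name, so inserting a stage never reshuffles another stage's
  randomness.

## Problem sizes used in the shipped checks

The automated checks run on scaled-down cohorts chosen to exercise the
same operating regime as the emulated study: screening calibration on
5,000 genes at the 135-sample discovery layout, end-to-end discovery
on 5,000 genes × 199 samples with 10 planted prognostic genes
(|β| = 0.8), cut-point recovery at n=400 over 50 replicates, log-rank
calibration over 1,000 null replicates and a 10,000-permutation
oracle.

## Known limitations

* The MC-CV joint criterion (mean Wald P < 0.01 over 200 half-sample
  fits plus >80% sign consistency) is conservative: with ~45 discovery
  events, genes whose marginal per-SD log-hazard is ≈0.5 have well
  under 50% selection probability. In multi-gene cohorts the composite
  exp(β·x) frailty attenuates each gene's marginal coefficient below
  its conditional β, so planted-gene recovery saturates around 6–7 of
  10 even at conditional |β| = 0.8.
* PAM chance intersections scale as `n_genes · (top_k/n_genes)² / 2`;
  holding `top_k = 300` while shrinking the gene count below the
  ~22,000 probes of the emulated platform inflates the screen's false
  positive rate accordingly. On down-scaled cohorts `top_k` should be
  scaled with the platform size if the original stringency is wanted.
* Native scoring algorithms of the commercial comparison signatures
  (Oncotype RS, GGI, Mammaprint) are out of scope; all comparison
  signatures are evaluated under the common sign-corrected index, as
  in the protocol being reproduced.
* No time-varying covariates, stratified Cox or proportionality
  diagnostics.
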