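# Methods

## Conditions and POI matrices

The canonical condition scheme fixes 12 conditions in a deterministic
order: indices 0–8 are the motion-aftereffect (MAE) test-image conditions,
direction-major — (approach, recede, static) × (negative, neutral,
positive) — and indices 9–11 the adaptation videos (contract, expand,
alternate). A contracting video yields an approaching aftereffect and an
expanding video a receding one; the alternating video yields none.

A POI is compiled from declarative blocks over condition selectors. A
single-selector block sets every within-group pair, including the
within-condition diagonal, to its value; a two-selector block sets the
cross pairs symmetrically. Unlisted pairs take the default (0). Conflicting
assignments and empty selectors are specification errors, as is any −1 on
the diagonal (a condition cannot anticorrelate with itself). The default
library fixes each of the 13 POIs as the minimal block structure satisfying
its one-line definition; e.g. IV_Lin is +1 within the positive and negative
image sets and −1 across them, OV_Pos is a single +1 block over
{approach-positive, recede-negative}. Two optional POIs (PM_App, PM_Rec —
perceived approach / recession alone) ship outside the default library,
which deliberately matches the 13 canonical columns. All compiled matrices
are exportable as labelled CSV, and user libraries can be supplied as JSON
specs.

## Synthetic data generator

The generator works at the condition-covariance level, not the time-series
level: no HRF, trials, or GLM estimation. For subject s with jittered
weights w_{s,i} ~ N(w_i, τ²),

    C_s = w0·I + Σ_i w_{s,i}·P_i,

eigen-clipped to the positive-semidefinite cone if needed (a flag reports
whether clipping changed the matrix by more than 1e−10). Each voxel's
12-vector signal is drawn i.i.d. from N(0, C_s); each run observes the
signal plus independent N(0, σ²) noise per voxel and condition. Defaults
mirror the study design: 19 subjects, 6 runs, 800 voxels (ROI sizes in the
emulated study span ~50–2,000), w0 = 1, σ = 1, τ = 0.05 in the study-like
preset. The "MT-like" preset plants weights 0.370 / 0.099 / 0.150 / −0.038
on RM_NS / Set / IV_All / IV_Lin.

Parameter meanings (all dimensionless, betas are percent-signal-change-like):

* **w0 (baseline_weight ≥ 0)** — shared within-condition signal variance;
  sets cross-run pattern reliability (diagonal similarity
  atanh(w0'/(w0'+σ²)) where w0' is the condition's total signal variance).
  w0 = 0 yields pure-noise data, useful as a strict null.
* **w_i (poi_weights)** — covariance contribution of POI i; the planted
  "effect size".
* **σ (run_noise_sd)** — per-run voxel noise; together with w determines
  the expected similarity z ≈ atanh(C_ij/√((C_ii+σ²)(C_jj+σ²))).
* **τ (subject_weight_sd)** — between-subject SD of each w_i; jitter is on
  weights, not patterns, so group-level weights stay interpretable targets.

What the generator emulates: the subject/run/condition/voxel layout,
planted mixtures with between-subject variability, and run noise. What it
does not: spatial voxel correlation (Pearson-over-voxels is invariant to
voxel order, so smoothness only rescales the effective voxel count),
hemodynamics, session drifts, or shared run-level components (an
independent-noise-per-condition default keeps same-run and cross-run pair
expectations equal). Passing recovery tests on this generator therefore
demonstrates the statistical machinery, not robustness to fMRI artifacts.

`expected_similarity` gives the closed-form Fisher-z expectation for τ = 0
and is the analytic oracle for the simulation tests (off-diagonal
z = atanh(C_ij/√((C_ii+σ²)(C_jj+σ²))), diagonal z = atanh(C_ii/(C_ii+σ²))).

## Similarity stage

Pearson correlations are computed over voxels between every admissible run
pair: for distinct conditions, all run pairs including same-run (36 for 6
runs; a `cross_run_only` switch drops same-run pairs); for a condition with
itself, distinct-run pairs only (15), since a pattern's same-run
self-correlation is 1 by construction. Correlations are clipped to
|r| ≤ 1 − 1e−6 (keeps z finite in noise-free edge cases) and Fisher
transformation is applied per run pair *before* averaging — the
variance-stabilizing-first convention; a regression test guards the
average-in-z choice. Vectorization takes the upper triangle including the
diagonal, row-major: 78 cells, so 9 stacked hold-out subjects give
702 observations and a simple regression with 700 residual df.

## Component model

Stacked cells are modelled as

    z_cell = α + b·d + Σ_j γ_j·D_j + Σ_i β_i·P_i^off + u_subject + ε,

where d is the within-condition indicator (the vectorized identity — the
usual baseline/noise component of pattern-component modelling), {D_j} is a
shared **reliability dictionary** (the deduplicated diagonal-support
patterns of the whole library, kept while they add design rank), and
P_i^off is POI i's between-condition (off-diagonal) part, whose coefficient
β_i is the reported contributing weight. u_subject is a random intercept,
estimated by maximum likelihood (ML, not REML — REML likelihoods are not
comparable across fixed-effect structures). BIC = −2·loglik + k·ln(n) with
k counting every estimated parameter (all fixed effects plus residual and
random-intercept variances) and n the stacked cell count.

Two design choices deserve justification:

* **Why separate reliability terms?** Diagonal cells measure cross-run
  pattern reliability. Under the generative model their Fisher-z is a
  *different nonlinear function* of signal strength than the z of a
  between-condition correlation (atanh(C_ii/(C_ii+σ²)) vs
  atanh(C_ij/(C_ii+σ²)-type ratios), so no single β per POI can satisfy
  both; forcing one coefficient makes the residual systematic at realistic
  voxel counts and the BIC search then recruits spurious POIs to absorb it.
  Decoupling representational geometry (off-diagonal) from reliability
  (diagonal) makes a single planted POI's expectation exactly linear in
  the design.
* **Why a dictionary shared across candidate models?** If each candidate
  carried only its own diagonal columns, differences in how candidates'
  diagonal support absorbs reliability variance would leak into BIC and
  bias selection toward particular POIs even under a null. With the
  dictionary fixed, all models see identical diagonal structure and
  comparison is purely about between-condition evidence.

`include_baseline=False` / `split_diagonal=False` recover the raw
one-column-per-POI design (used by the closed-form BIC unit tests), and
`method="pooled"` replaces the mixed model with pooled OLS (used by the
exhaustive-search oracle). The random-intercept ML fit is computed by a
profiled one-dimensional likelihood optimization (whitening
y − c·ȳ_group with c = 1 − 1/√(1+θm), θ = τ²/σ²) — exact ML, verified
against statsmodels MixedLM (reml=False) to ~1e−5 in log-likelihood — and
roughly 50× faster, which matters because a full MCCV run makes ~10⁴ fits.

Rank-deficient candidate sets (e.g. duplicated POIs) are inadmissible, not
pseudo-inverted: an unidentifiable β cannot be reported as a contributing
weight.

## Selection

Greedy best-first search on BIC with Δ = 2:

* Level 1 fits every single POI. The best single seeds the search **only
  if it improves BIC by more than Δ over the null (no-POI) model**;
  otherwise the contributing set is empty. Without this gate every run of
  the search would nominate some POI even on pure noise, and resampled
  subsets of one dataset would concentrate those nominations on whichever
  POI is noisiest in that sample.
* Seeds and additions within Δ of the best admissible one are
  statistically equivalent and branch into parallel paths; paths reaching
  the same POI set are merged (otherwise k equivalent seeds would always
  complete k! permutation duplicates), and `n_paths` counts distinct
  completed paths ("Av. n-path" averages it over MCCV iterations).
* A path completes when no remaining POI improves its BIC by more than Δ.
  The contributing set is the completed path with the lowest end BIC;
  exact ties prefer fewer POIs, then lexicographic order (flagged on the
  result).

The reconstructed component is the fitted model's prediction minus the
global intercept: Σ β_i·P_i^off plus the baseline and reliability terms, so
it predicts diagonal and off-diagonal hold-out cells on the same footing;
the hold-out fit estimates a fresh intercept and slope by simple least
squares and reports R², F(1, 78·n_HO − 2), p.

## Monte-Carlo cross-validation

Splits are drawn without replacement within an iteration and independently
across iterations (duplicates across iterations permitted), all from one
seed; all splits are drawn up front so results are independent of
evaluation order. "Identified" means present in the best completed path of
that iteration. Chance rate = mean contributing-set size / library size.
Hold-out statistics aggregate over iterations with a non-empty selection.
The summary masks a POI's mean β unless its identification count beats the
chance rate in a one-sided exact binomial test at α = 0.05 (per column,
display convention); the package's own null-calibration test instead
controls the family-wise rate across the 13 POIs (Bonferroni), since the
claim there is joint. The summary's p column is the median per-iteration
hold-out p (iterations share subjects, so combining p-values as if
independent would be wrong).

## Problem sizes in the test suite

The validation suite runs: greedy-vs-exhaustive agreement on 100 datasets
with 3–5 orthogonal POIs (6 subjects, 600 voxels, pooled fits);
single-POI recovery on 100 datasets (w = 0.4, σ = 1, τ = 0.05, 2,000
voxels, 10 subjects); the MT-like mixture with 200 MCCV iterations
(19 subjects, 800 voxels); analytic agreement at 5,000 voxels and 16
subjects for 10 random weight configurations (≥95% of cells within 3
Monte-Carlo SEs — among 780 comparisons a few >3-SE excursions are
expected even under a perfect implementation — and none beyond 6 SEs); and
a 200-iteration null run. These sizes keep the full suite at a few minutes
on one CPU while leaving each check well-powered.

## Known limitations

* Similarity cells that share a condition are correlated through the
  finite-voxel sampling of that condition's signal; the residual model
  (random intercept + i.i.d. noise) ignores this, which makes the BIC
  search mildly anti-conservative. Concretely, with no between-subject
  weight variability (τ = 0) the single-POI scenario admits one spurious
  overlapping POI in ~10% of replicates; at the study-like τ = 0.05 this
  drops to ~4%. A subject×condition random-effect structure would model
  the correlation directly, at substantial fitting cost.
* MCCV iterations resample one subject pool, so identification rates are
  dependent across iterations; binomial tests against chance treat them as
  independent and should be read as descriptive, not exact.
* Contributing βs are on the Fisher-z scale of the similarity cells; they
  recover the planted covariance weights' sign and ordering, not their
  numeric values.
* atanh averaging over run pairs carries a small positive bias of order
  ρ/(2V); at the voxel counts used it is far below the Monte-Carlo SE.
* The NIfTI route reads one 3-D volume per (subject, run, condition);
  4-D stacks are out of scope, as are searchlights, distance metrics other
  than Pearson, and noise-normalized (crossnobis) variants.
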