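# Methods

This note documents the generative model, the analysis chain, the
parameter choices, and the known limitations of `hemilat`.

## 1. Generative cohort model (`hemilat.population`)

Each simulated participant has `V` voxels per hemisphere (default 50),
indexed so that voxel *i* on the left is homotopic to voxel *i* on the
right, and six stimulus categories: faces, words, inverted words, letter
strings, objects, scrambled. Geometry is abstract — voxels carry only
hemisphere and parcel labels, since every analysis operates on masked
aggregates.

**True laterality indices.** Per participant, the vector of per-category
true LIs is drawn as `li = clip(mean + sd · z, −0.999, 0.999)` with
`z ~ N(0, C)` for a target correlation matrix `C` (a Gaussian copula with
a linear margin, so `C` is preserved exactly in population before the
rare clip). Defaults: faces mean −0.25 (rightward), the three text
conditions +0.3 (leftward), objects −0.05, scrambled 0; SD 0.2 for all;
`C = I` (independent LIs).

**Voxel tuning.** For every voxel, a latent standard-normal vector across
categories with correlation given by the `overlap` matrix (default 0.2
off-diagonal) is mapped through a mean-one lognormal transform
(`log_sd = 0.5`). Overlap 1 makes category maps identical; overlap 0
makes them independent.

**Lateralization by hemisphere gains.** The right-hemisphere tuning
pattern is a mirror copy of the left (optionally perturbed by
`pattern_asymmetry`). Lateralization multiplies each hemisphere's map by
a gain: with `A_H` the hemisphere's summed tuning and `T = A_L + A_R`,

```
g_L = (1 + li) · T / (2 A_L),   g_R = (1 − li) · T / (2 A_R),
```

which makes the LI of summed amplitudes equal the drawn `li` *exactly*
while conserving the bilateral total. Because the mirror makes the
per-voxel left/right amplitude ratio constant, the summed, peak, and
count versions of the LI all agree with the drawn truth — the model has a
single well-defined ground truth per category.

**Shared (arousal) component.** A separate mean-one lognormal map, scaled
by `shared_activation_amplitude` (default 0.5) and lateralized by its own
per-participant LI (`N(0, 0.2²)`, same gain construction), is added to
*every* stimulus condition's response. This is the generative source of
the fixation-baseline confound. Rest blocks carry zero signal.

**Handedness.** Edinburgh scores `N(86.9, 16.5²)` clipped to
[−100, 100], matching a predominantly right-handed cohort.

## 2. Stimulus design (`hemilat.design`)

Each run presents 6-s mini-blocks back to back (lead-in 10 s, tail 14 s,
TR 2 s, 5 runs). Block order is fully counterbalanced: every ordered pair
of distinct conditions is adjacent exactly once per run. Such an order is
an Eulerian circuit on the complete digraph over conditions; we sample one
uniformly-supported circuit per run with Hierholzer's algorithm using
randomized edge order and start vertex. A rest condition participates in
the counterbalancing like any stimulus, so k = 7 conditions give
k(k−1)+1 = 43 blocks and 141 TRs per run (705 total).

## 3. Forward simulation and GLM (`hemilat.timeseries`, `hemilat.glm`)

Per voxel, the neural signal is the sum over conditions of block boxcars
weighted by (category amplitude + shared component), convolved with a
canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 1/6, 32 s support, unit peak), sampled on
the TR grid from a 0.1-s oversampled grid; the convolution is a Riemann
approximation of the continuous integral (scaled by dt). Additive noise
is Gaussian, optionally AR(1) (default white, SD 4 — see §6).

The GLM uses one task column per condition × run (identical construction
to the simulator's signal basis, which makes noiseless recovery exact),
per-run mean columns, optional per-run cosine drifts, and user nuisance
columns (mean-centered per run). Fitting is per-voxel OLS; t-statistics
are `c'β / sqrt(σ̂² c'(X'X)⁻¹c)` with df = T − rank(X). Optional AR(1)
prewhitening is one Cochrane–Orcutt pass with a single coefficient pooled
over voxels, quasi-differencing within runs. When the simulation is
noiseless, σ̂² is numerically zero and maps are reported as contrast
*effects* (`c'β`) rather than t-values; all downstream thresholds then
reduce to sign tests.

## 4. Contrasts, selectivity, laterality (`hemilat.contrasts`, `.selectivity`, `.laterality`)

Three domains are compared pairwise: faces, objects, and a text composite
whose beta is the equal-weight mean of words, inverted words, and letter
strings. Per domain, three baselines:

* **full** — domain vs. the balanced mean of the other two domains
  (faces: `F − (T + O)/2`, the text half-share spread as 1/6 per text
  condition);
* **heldout** — domain vs. one designated third domain;
* **fixation** — the domain's betas against implicit rest (nonnegative
  weights only).

Weights are laid over (condition, run) beta columns and summed over the
runs of a split — odd {1, 3, 5} or even {2, 4} — so the two sides of any
cross-participant comparison use disjoint data. Selectivity `S_{C,H}` is
computed inside the intersection of an anatomical mask and a
stimulus-responsive mask (one-sided p < 0.001 on the omnibus
all-stimuli-vs-rest map, balanced over conditions) as the sum of positive
statistics, the peak statistic floored at 0, or the count of
supra-threshold voxels. `LI = (S_L − S_R)/(S_L + S_R)`, NaN when both
sides are zero (excluded pairwise from correlations, with the exclusion
count reported).

Cross-participant analyses: Pearson for pairwise LI correlations,
Spearman for split-half reliability and parcel analyses. Residualization
regresses a third category's fixation LI (taken from the *same* split as
the LI it is removed from) out of both sides before correlating. Parcel
coupling correlates each homotopic parcel-pair's LI (one split) with a
target region's LI (the other split), with Benjamini–Hochberg FDR across
parcels. Handedness sweeps re-estimate a pairwise correlation over
participants above a sliding Edinburgh threshold.

### Responsive-mask policy

The responsive mask is computed once per participant from all runs by
default (standard localizer practice); `mask_policy="per-split"` computes
it per run split instead. The bias experiments default to per-split
masks: a mask shared between splits injects a common factor into both
sides of a nominally independent comparison (see §6).

## 5. Bias and recovery experiments (`hemilat.bias`)

A `BiasExperimentConfig` fixes a grid over (true cross-domain correlation
ρ, tuning overlap, shared-activation amplitude, noise SD) and, per grid
point, simulates `n_replicates` cohorts of `n_subjects` (defaults
200 × 200, 30 voxels per hemisphere for speed), runs the full
simulate → GLM → selectivity → LI chain, and estimates the faces–text
correlation under each baseline scheme plus the residualized fixation
scheme. The condition-level LI correlation matrix ties the three text
conditions together (correlation 1) and sets the faces–text block to ρ,
so the domain-level truth is exactly ρ. Summaries report mean/SD of the
estimate, bias, RMSE, Fisher-z CI coverage, and one-sided sign-test
p-values. Replicates are seeded with `SeedSequence([seed, grid_index,
replicate])` — reproducible and order-independent.

* **Null-bias experiment** (ρ = 0): isolates each baseline's confound.
  Expected signature, confirmed by the acceptance suite: full negative;
  heldout positive; fixation positive when the shared component is on and
  unbiased (|mean r| ≤ 0.05) when it is off; residualization shrinks the
  fixation bias.
* **Recovery experiment** (ρ ∈ {−0.5, 0, 0.5}, shared component off):
  checks that the residualized fixation scheme recovers the true
  correlation (|bias| ≤ 0.1, RMSE ≤ 0.15 at n = 200). The shared
  component is off because with it on, the confound documented by the
  null-bias experiment is *supposed* to bias the estimate; the recovery
  experiment isolates estimation quality in the unconfounded regime.

## 6. Numerical and calibration choices

* **Noise SD 4.0 (default).** Two constraints pin this down. First,
  split-half LI reliability must be high (Spearman ρ ≈ 0.95–0.98 at the
  default geometry), consistent with reliable individual differences.
  Second, per-voxel omnibus detection must be essentially complete: every
  simulated voxel is genuinely responsive by construction, so
  sub-threshold voxels are pure Type-II error — and they are not harmless.
  The missed voxels concentrate in the lower-gain hemisphere, so the
  responsive mask's hemispheric extent tracks the participant's
  category-*average* lateralization; since summed selectivity is
  extensive in voxel count, every category's measured LI absorbs that
  common factor. At noise SD 12 (mask fill ≈ 0.7) this mask-extent
  leakage alone produced a spurious faces–text correlation of ≈ +0.5 in
  an otherwise fully independent regime; at noise SD 4 masks are
  ≈ 99–100 % full per split and the regime is unbiased (mean r ≈ +0.02).
  The residual +0.02 comes from the remaining ≈ 1 % mask misses and
  t-statistic selection effects.
* **30 voxels per hemisphere in bias experiments** (50 in the default
  population): keeps a 200 × 200 replicate suite under two minutes on one
  CPU. Mask-extent leakage shrinks with voxel count, so the small-ROI
  setting is conservative (worst case) for that artifact.
* **Oversampling dt 0.1 s** for boxcar construction; block onsets align
  with the grid exactly at the default timing.
* **Pooled AR(1)** (single coefficient across voxels, one
  Cochrane–Orcutt pass) rather than per-voxel whitening: adequate at
  desk scale, and the default simulations use white noise.
* **Degenerate-noise handling**: zero-noise simulations switch all maps
  to contrast effects; thresholds become sign tests; LIs are exact.

## 7. Limitations

* Voxels have no spatial structure: no smoothing, no spatial noise
  correlations, no partial-volume effects; "parcels" are index ranges.
* The mirror-hemisphere construction plus gain scaling is the simplest
  model satisfying the LI and overlap constraints; real topographies
  differ between hemispheres in location and extent, not just gain
  (`pattern_asymmetry` perturbs the mirror but is 0 by default).
* Noise is independent across voxels and conditions; shared residual
  noise within a run (which further inflates fixation-baseline
  correlations in real data) is not modeled.
* The GLM and the simulator share the same HRF and regressor
  construction, so HRF misspecification is out of scope.
* Count selectivity at the default p < 0.001 threshold is near-degenerate
  in high-SNR simulations (all voxels supra-threshold in both
  hemispheres → LI ≈ 0); it is exposed for completeness, and the summed
  metric is the default everywhere.
* The bias magnitudes depend on the assumed reliability, overlap, and
  arousal amplitude; the suite exposes these as grids precisely because
  their realistic values are uncertain.
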