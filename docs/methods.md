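# Methods

This note records the models, conventions and numerical choices behind
`fidelitylink`, what the synthetic generator does and does not emulate, and
the known limitations.  Nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic world

`synthdata` generates a paired-associates study: four dynamic stimuli per
modality, presented 12 times each in 48-trial blocks (four blocks,
alternating visual/auditory), followed by cued recall with a 1–4 confidence
rating.  A pair counts as *remembered* when the response is correct **and**
confidence exceeds 1; the `remembered` column equals
`correct & (confidence > 1)` on every row by construction.  The default
memory rate is 0.634, the behavioural mean of the paradigm the generator
emulates.

Each trial carries a latent **fidelity** `f_t ∈ [0, 1]`, Beta-distributed
with mean 0.5 and SD 0.2 by default.  The Beta family was chosen because it
is bounded like a fidelity should be and its variance can be shrunk to probe
the restricted-variance (attenuation) regime; the true distribution in real
data is unknown, so the choice is exposed in configuration.  Fidelity scales
the trial's noise-free pattern `f_t · μ_s(t)`, where the prototypes `μ_s`
form an equal-norm simplex with all pairwise Euclidean distances equal to
`separation` (default 3.0 in the pipeline driver, which yields a moderate
trial-information signal against unit-variance voxel noise).

Voxel noise is Gaussian, temporally white, spatially correlated with a
geometric decay (unit-lag correlation 0.3) — a deliberately simple
positive-definite stand-in for smooth scanner noise.  BOLD forward
simulation uses a boxcar of the 3 s event duration at TR = 2 s convolved
with the canonical double-gamma HRF.  Electrophysiological epochs are
coloured noise with PSD ∝ f^(−χ) (synthesised by scaling the FFT of white
noise by f^(−χ/2), DC bin zeroed) plus a random-phase sinusoid.

Trial power follows
`post_t = a − β·f_t + γ_c·conf_t + γ_b·bold_t + ε_t` with ε Gaussian
(SD 0.3 by default, giving a power–fidelity correlation of ≈ −0.55 at the
default β = 1, a deliberately moderate coupling).  Pre-stimulus power is
independent noise; confidence is an ordinal 1–4 rating obtained by
quartile-thresholding a latent Gaussian correlated 0.3 with fidelity, so
the confidence-nuisance path carries real signal.

**What the generator does not emulate:** haemodynamic nonlinearity, scanner
drift, physiological noise, EEG artifacts, volume conduction and source
leakage, temporal autocorrelation of fMRI noise, non-Gaussian noise.
Passing tests therefore demonstrate correctness and calibration of the
*statistics* under the stated model, not robustness to every property of
real recordings.

## Pattern estimation (glm)

Least-squares-all estimation: one model with one regressor per condition or
per trial (a configuration switch; a least-squares-single variant is not
implemented).  Events are boxcars at dt = TR/16, convolved with the
double-gamma HRF (response peak 6 s, undershoot 16 s, ratio 6 — the
de-facto canonical parameterisation), downsampled to the TR grid, plus an
intercept per run in lieu of a full preprocessing chain.  Rank deficiency
raises an error naming the offending columns.  Residuals are returned for
covariance estimation.

## Crossnobis distances and information (rsa, trialinfo)

The noise covariance is the sample covariance of residuals shrunk toward
its **diagonal**, `Σ* = (1−λ)S + λ·diag(S)`, with λ the analytic optimal
intensity (ratio of summed sampling variances of off-diagonal entries to
their summed squares) clipped to [0, 1] — positive definite even with fewer
samples than voxels.  Residuals (rather than condition-demeaned patterns)
are the covariance source; this is a configuration-level choice.

Cross-validated Mahalanobis distance uses the bilinear form
`d(j,k) = Δ_jkᴬᵀ Σ*⁻¹ Δ_jkᴮ`; because `Σ*⁻¹` is symmetric this already
equals the average over both fold assignments.  Same-condition cross-fold
entries `d(j,j)` are identically zero and are *included* in the model
correlation (16 cross-fold pairs for 4 stimuli), which keeps the
information statistic exactly centred under the null.

**Sign convention** (stated once, tested in the perfect-separation cases):
distances are correlated against the 0/1 dissimilarity model (0 = same
stimulus, 1 = different), so informative patterns give ρ > 0, and
information is `z = atanh(ρ)` with |ρ| clipped at 1 − 1e-10.  Spearman uses
average ranks for ties; with a binary model the correlation has a closed
form used by the vectorised implementation (`_utils.spearman_rows_binary`).

Trial-level distances require discriminant weights independent of the
patterns they are projected onto:

* *Perception*: trial t is compared with every trial u of the other fold;
  the weight is `Σ*⁻¹(m_{s(t)} − m_{s(u),−u})` built from u's-fold condition
  means with u left out of its own mean.  For same-stimulus pairs the weight
  (and hence the distance) is identically zero — there is nothing to
  discriminate — which preserves exact null calibration; under signal the
  differing-pair distances are positive and the ordering still carries the
  information.
* *Retrieval*: each remembered retrieval trial is compared with every
  perception trial; the weight pairs the stimulus-averaged retrieval
  pattern with the perception condition mean of the partition *not*
  containing the comparison trial.  The only term reusing the projected
  trial is constant across its comparisons and therefore invisible to the
  rank correlation, so no leave-one-out correction is needed there.

Searchlights use inclusive Euclidean distance on the acquisition grid
(3×3×4 mm): a 10 mm sphere holds 121 voxels, and centres holding less than
60 % of the full analytic count are discarded.  ROI dilation takes the
union of the member sets of every searchlight centred in a cluster.

Group-level map inference is a voxelwise one-sample t with sign-flip
permutation max-cluster-mass correction rather than random-field theory;
the permutation route is dependency-free and exactly calibrated under the
symmetry of the null.

## Spectral estimation (spectral)

Complex Morlet wavelets with `σ_t = n_cycles/(2πf)` (6 cycles), unit-energy
normalisation, support ±5σ_t; power is the squared magnitude of the
convolution.  Edge samples whose wavelet support leaves the epoch are
flagged, not padded — the canonical analysis windows avoid them.  The
z-baseline subtracts the mean and divides by the SD of power over times and
trials jointly, per electrode × frequency.  Band/window averaging defaults
to 8–30 Hz with 500–1500 ms (post) and −1000 to −375 ms (pre) windows;
theta (3–7 Hz) and gamma (40–50 Hz) variants are parameterisations, not
separate code paths.

IRASA: for each resampling factor h in 1.1–1.9 (step 0.05), the geometric
mean of the PSDs of the h- and 1/h-resampled signals leaves a power law
invariant while displacing narrow-band peaks; the median across the factor
set is the fractal component and the residual is the oscillatory component
(their sum reproduces the original PSD by construction).  PSDs use
Hann-windowed Welch averaging with 50 % overlap; the segment length is
min(1 s, epoch) further capped by `n/h_max` so every resampled copy shares
one frequency grid.  The log-log slope/intercept fit runs over 1–25 Hz by
default, and the top of the fit band must stay below `fs/(2·h_max)` (≈ fs/4)
— the highest frequency the slowest resampled copy can represent.
Oscillatory band power is the mean over 8–25 Hz.  A strong oscillation with
very weak background noise leaks slightly into the fractal estimate (finite
factor sets cannot remove a peak entirely); the slope-separation test uses
a realistic noise floor for this reason.

The epoch-length reliability study regenerates pure-1/f epochs of
increasing duration and reports the mean and SD of the fitted slope per
length: short (~1 s) epochs give unreliable estimates, and the SD shrinks
monotonically toward 60 s.

## Inference (stats)

Per-participant regression: OLS with intercept, predictors z-scored,
complete cases only (dropped rows logged); t = β̂/SE.  The median-split
control replaces continuous post-stimulus power with an above-median
indicator.  Participants with fewer than `regressors + 2` usable trials,
or with fewer than 10 remembered or 10 forgotten trials
(`apply_participant_exclusion`), are excluded with a logged reason —
never imputed.

Group test: one-sample sign-flip permutation t-test;
`p = (#{as or more extreme} + 1)/(n_perm + 1)` (the +1 guarantees validity
at finite n_perm); exhaustive 2ⁿ enumeration replaces sampling for n ≤ 12.
The power regressor is tested left-tailed (the hypothesised direction is
negative); nuisance regressors two-tailed.  Cluster-based permutation
testing thresholds feature-wise t at the cluster-forming quantile
(α = 0.05 default), groups supra-threshold features under lattice or
user-supplied adjacency (isolated features form singleton clusters), sums
t within clusters ("maxsum") and compares against the sign-flip null of
maximal cluster mass.

The JZS Bayes factor integrates the Cauchy-prior (r = 0.707, the JASP
default, configurable) g-mixture by adaptive quadrature with relative
tolerance 1e-10; an error is raised if the integral does not converge.  It
depends on the data only through |t| (two-sided formulation).  Interpretive
labels follow the usual anecdotal/moderate/strong bands.

The power–confidence correlation uses Spearman (the ratings are ordinal)
with Fisher z, then the group permutation test.

The attenuation study draws Gaussian fidelity at a series of SDs and
compares the mean observed power–fidelity correlation with the closed form
`ρ = −βσ_f / sqrt(β²σ_f² + σ_ε²)`; at σ_f = 0 the sample correlation is
undefined and reported as 0.  Comparisons allow the classical O(1/n)
shrinkage bias of the sample correlation.

## Simulation sizes

Calibration and recovery studies were sized to give tight Monte-Carlo error
at desk scale: 2 500–5 000 null simulations per calibration (SE of a 5 %
rate ≈ 0.3–0.45 percentage points), 50 replicate studies for detection
power and 150 for the null rate at the moderate regime (21 participants ×
100 trials, fidelity SD 0.2, β = 1), 30 repetitions per epoch length for
the 1/f reliability table, and 400 replicates of 500 trials per
attenuation level.  The replicate studies use 1 000 permutations per group
test; single demonstration fits use 2 000.

## Known limitations

* Trial-level crossnobis weights discard same-stimulus discriminative
  signal at perception (the degenerate-weight construction); this is the
  price of exact null calibration with only two folds.
* The GLM has no autocorrelation model (fMRI noise is treated as white),
  no motion/nuisance regressors, and least-squares-all only.
* IRASA slope estimates on sub-5 s epochs are intrinsically unreliable —
  reproduced, not fixed, by this package — and single-trial aperiodic
  regressors should be interpreted accordingly.
* The cluster permutation test assumes exchangeability under sign flips
  (symmetric per-participant nulls), as does the group test.
* NIfTI export writes a plain diagonal affine (3, 3, 4) mm; no registration
  or normalisation is provided.
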