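# Methods

`nirswalk` implements a complete walking-task fNIRS functional-connectivity
analysis: forward simulation of dual-wavelength optical recordings with a
planted region-level correlation structure, the five-step preprocessing chain,
channel-pair Pearson connectivity aggregated to six cortical regions, and the
group-comparison and gait-correlation statistics. This note documents the
models, the parameters that matter, and the design decisions behind them.

## Study design being modelled

Two groups — 30 people with Parkinson's disease (PD) measured in the off-state
and 22 healthy controls (HC) — each perform three trials of 30 s standing,
35 s walking, 10 s standing. A wearable continuous-wave fNIRS system records
30 channels (14 sources, 12 detectors, 3 cm separation) at 730/850 nm and
11 Hz over six regions: left/right prefrontal (LPFC, RPFC), premotor (LPMC,
RPMC), and primary somatosensory cortex (LPSC, RPSC). Spatiotemporal gait
parameters (cadence, double support, gait-cycle duration, gait speed, stride
length, per foot) are consumed as a per-subject table. One source text gives
the walking duration as 30 s in its summary and 35 s in its methods; the
methods value (35 s) is used.

## Montage

The exact probe geometry is not machine-readable from the source figure, so
the default montage assigns 5 channels per region (the unique uniform
partition of 30 channels over 6 regions) with left/right symmetric numbering
and a realistic optode wiring (7 sources + 6 detectors per hemisphere, two
channels reusing a neighbouring optode). Every computation downstream depends
only on the channel-to-region partition; scalp coordinates are optional
metadata. Montages are serialisable to JSON so a figure-faithful layout can be
substituted, and the channel wiring can be reconstructed from SNIRF
measurement lists (SNIRF carries no region labels, so those must accompany
real data as a montage file).

## Preprocessing chain

Steps run in this order, each on the previous step's output:

1. **Motion-artifact detection and correction** (on optical density).
   A sample is flagged when the moving-window amplitude range *or* moving SD
   (window 1.0 s) exceeds 5.0 x a robust scale (1.4826 x MAD of the series);
   flags are dilated by 0.5 s and unioned over wavelengths. Within each
   flagged segment a near-interpolating cubic smoothing spline is subtracted
   and the segment re-anchored to the preceding clean sample; samples after
   the segment are then shifted to restore continuity at the segment end.
   This is the standard spline (MARA-style) scheme: it removes both spikes
   and baseline steps. Re-levelling the tail means samples after an artifact
   are translated by a constant — the price of removing step artifacts, and
   immaterial to band-passed, baseline-corrected analyses.
2. **Bandpass** 0.01-0.2 Hz, 3rd-order Butterworth applied forward-backward
   (zero phase, so connectivity sees no filter-induced lag). Measured on
   probe sinusoids: >= 40 dB attenuation at 1.1 Hz (cardiac), < 0.01 dB loss
   at 0.05 Hz.
3. **Modified Beer-Lambert conversion.** Per channel and sample the 2x2
   system dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] x d x
   DPF(lambda) is solved for (dHbO, dHbR) in uM, with d = 3 cm. Extinction
   coefficients (1/(mM cm), 730/850 nm) and DPF (6.0/5.2) are standard
   literature values; neither is identifiable from correlation-based
   connectivity (Pearson r is scale invariant — asserted by a test that
   rescales DPF +-20%), so they only set the reported concentration scale.
   Filtering before the conversion means the filter acts on optical density;
   both operations are linear, so the order does not change the result, but
   the printed order is preserved and recorded in provenance.
4. **PCA systemic removal.** Channels are mean-centered and the first
   principal component across channels is projected out (k = 1 by default;
   k = 0 disables, larger k allowed). This targets spatially coherent
   systemic physiology — scalp blood flow and Mayer-band blood-pressure
   oscillations — that survives the bandpass because it overlaps the
   analysis band. Applied per recording (per trial), before block
   extraction.
5. **Walking-block extraction.** dHbO over [30 s, 65 s) (index = floor(t x
   fs), half-open, 385 samples), minus the per-channel mean of the last 5 s
   of the pre-walk stand.

Optical density uses the recording-mean intensity as reference, so the
Beer-Lambert inverse reproduces planted concentrations only up to an additive
per-channel constant (10^(-x) is nonlinear, so the mean intensity is not the
nominal source intensity). The constant is irrelevant downstream: the
bandpass removes DC and the walking block is baseline-corrected.

## Connectivity

Pearson correlation between every pair of channel walking blocks, averaged
over (a) the C(5,2) = 10 unique channel pairs inside each region (6
within-region values), (b) the 5 x 5 = 25 cross pairs of each region pair (15
between-region values), then (c) the three trials. Raw r values are averaged
— no Fisher z (a z mode exists behind a flag) and no rectification of
negative values, matching the plain reading of "averaged" and group means in
the 0.3-0.5 range. Correlating per trial and then averaging (rather than
concatenating trials) is the default; concatenation is available. Channels
with zero variance are masked and excluded from the pair means with a logged
count.

## Synthetic cohorts: generative model

The generator's purpose is parameter recovery: the planted region-level
connectivity must be the estimand of the pipeline, so that recovering it
end-to-end validates every stage at once.

**Subject targets.** Each group has mean within-region correlations
(PD: LPFC .40, RPFC .42, LPMC .48, RPMC .43, LPSC .52, RPSC .53; HC: .34,
.37, .42, .37, .44, .51) and mean between-region correlations for all 15
pairs. Eight pairs have published group means (e.g. PD LPFC-LPMC .39 vs HC
.30); the seven unreported pairs default to values with a small (+0.03)
PD-HC gap, chosen once subject to the feasibility bound
between(R,S) <= sqrt(within_R x within_S) that the latent construction
implies.

A subject's within-region targets are Normal(group mean, target SD), where a
fraction (0.77) of the target SD is a single shared offset (subjects run
globally high or low) and the rest is region-specific. The subject's latent
region correlation matrix is the group matrix perturbed entrywise on
Fisher's z scale (SD 0.10) — the tanh keeps every entry inside the unit ball
— and shrunk toward the group matrix if the perturbation leaves the positive
semi-definite cone. Between-region targets follow as
latent x sqrt(w_R x w_S). This construction keeps every draw feasible
without one-sided censoring, so the group means of the achieved targets stay
centred on the specified group means; the naive alternative (drawing all 21
values independently and repairing the matrix afterwards) systematically
compressed the planted group separation, because high draws hit the
feasibility boundary and low draws do not.

**Observed vs target dispersion.** The per-measure SDs reported alongside
group means (typically ~0.13) describe the dispersion of *observed*
per-subject values, which mixes true between-subject variation with
single-subject estimation noise of the trial-averaged Pearson estimate
(~0.08 under this design, measured from the model). The generator therefore
plants target dispersion sqrt(0.13^2 - 0.08^2) ~ 0.10, so that observed
values disperse at the stated ~0.13. Treating the printed SD as pure target
dispersion would overshoot the observed dispersion and understate the
group-level stability the study reports.

**Channel signals.** Six band-limited (0.01-0.2 Hz) unit-variance latent
Gaussian processes are mixed to the subject's latent matrix; channel c in
region R gets sd x (sqrt(w_R) g_R + sqrt(1 - w_R) e_c) with independent
band-limited channel noise e_c and sd = 0.5 uM (typical background dHbO
fluctuation). Asymptotically the channel-pair correlation is w_R within and
sqrt(w_R w_S) G_RS between regions.

**The estimand correction.** The pipeline estimates correlation from 35-s
blocks whose signals are confined to 0.01-0.2 Hz; the number of effectively
independent samples is n_eff = 2T (int S)^2 / int S^2 ~ 11.4 (S the signal
power spectrum, here the Butterworth response to the 8th power since both
generation and analysis filter with the same zero-phase filter). The sample
correlation is therefore biased low: E[r] ~ rho - rho(1 - rho^2)/(2 n_eff),
a ~ -0.015 shortfall at rho ~ 0.5. The latent construction inflates
correlations by the first-order inverse of this expectation so that the
*planted target is the estimand* of the trial-averaged estimate. One further
term enters the recorded estimand: removing the leading principal component
(step 4) costs a small, calibrated slice of within-region shared variance
(-0.006; the component direction is estimated from ~800 samples and tilts
slightly toward the dominant neural direction — verified by the distortion
vanishing when the PCA step is disabled). The recorded ground truth is the
estimand under the default chain; residual bias measured over 24
calibration cohorts is below +-0.003 on every quantity.

**Task response and nuisance.** A canonical double-gamma HRF (peak 6 s)
convolved with the walking boxcar, amplitude 0.1 uM with per-channel gain
jitter U(0.7, 1.3), models the evoked response (modest relative to
background, as in over-ground walking). Cardiac (1.1 Hz, 0.15 uM) and
respiratory (0.25 Hz, 0.10 uM) sinusoids with random phases sit above the
band and are removed by the filter. The Mayer-band confound is a narrowband
~0.1 Hz global process (0.8 uM) with *zero-mean signed channel loadings*:
systemic oscillations across the scalp differ in amplitude and phase, and
the zero-mean loading makes the nuisance separable from the spatially
coherent neural structure, so the PCA step removes what it is meant to
remove instead of destroying the estimand. This is the one structural
assumption on which clean parameter recovery rests, and it is a property of
the simulation, not of real scalp physiology — see Limitations. dHbR is
-dHbO/3 plus noise (typical empirical ratio), recorded but not analysed.
Concentrations map to intensity through the forward Beer-Lambert model
(I = I0 x 10^(-dOD)) with 0.1% multiplicative measurement noise.

**Motion artifacts** arrive as a Poisson process (2/min) of optical-density
excursions on random single channels: half spikes (0.05-0.2 OD, 0.3-1 s,
Hann-shaped), half baseline steps (0.02-0.1 OD). Ground truth records every
artifact sample for detector sensitivity tests.

**Gait table.** Each variable is Normal(group mean, group SD) from the
published table, with left/right correlated at 0.95 and speed/stride at 0.8,
truncated at mean +- 4 SD and physical ranges (positive; percentages in
(0, 100); MMSE <= 30). Sex is Bernoulli at the published group male
fractions. In the PD group, gait speed and stride length carry a 0.445
loading on the subject's RPMC within-connectivity deviation, planting the
reported connectivity-gait association (absent in HC). The population Cohen's
d implied by the table parameters reproduces the published effect sizes
(e.g. gait speed L: -0.80 at equal large n; -0.77 at n = 30/22 weighting).

**Determinism.** All randomness flows from NumPy `SeedSequence` spawning
(PCG64): a master seed yields one stream per subject plus one for the gait
table; identical seeds give bit-identical cohorts.

## Statistics

Shapiro-Wilk per group and Levene across groups (alpha = .05) route each
variable to the two-sample t-test (both groups normal, variances
homogeneous) or the Mann-Whitney U test; the screen outcome is stored with
the result. Pooled-SD Cohen's d accompanies every contrast — the pooled
formula is the one that reproduces the published effect-size columns from
the published summaries, including the medication off/on contrast (1.32
with n = 30/30), which an average-SD or paired formula does not. Mann-Whitney
uses midranks with exact two-sided permutation enumeration when both samples
have <= 8 observations, otherwise the normal approximation with tie and
continuity correction; Kruskal-Wallis likewise enumerates exactly for small
samples (total n <= 10) and is followed by Dunn-Bonferroni post-hoc z tests.
Pearson correlations report r, R^2 = r^2, and the t-distribution p with
n - 2 df; connectivity-gait correlations are computed within group only, for
gait speed and stride length (left and right). No multiple-testing
correction is applied across the 21 connectivity contrasts by default
(matching the analysis being reproduced); Bonferroni/FDR are available.
Because the normality screen's outcome on unseen data is unknowable, the
published per-variable p-values are not reproduction targets; the effect
sizes are.

## What passing tests do and do not show

The synthetic cohorts demonstrate that the pipeline recovers a planted
region-level correlation structure through artifact correction, filtering,
chromophore inversion, and PCA under realistic noise, at the study's sample
sizes. They do not establish anything about real scalp physiology: real
systemic interference need not have zero-mean spatial loadings (global
interference makes PCA removal destructive to genuine connectivity — a known
hazard of global-component removal, not a defect of this implementation);
real artifacts are not single-channel Poisson events; real evoked responses
and connectivity need not be stationary within a block. Recovery tolerance
at the study's size is dominated by Pearson sampling noise (n_eff ~ 11 per
block), which no preprocessing can reduce; at 30/22 subjects the group-mean
estimates land within ~+-0.05 of planted values, with ~15% of cohort draws
producing one value just outside that band.

## Numerical choices

- Nearest-correlation repair: eigenvalue clipping at 1e-6 with diagonal
  renormalisation; group latent matrices instead use uniform shrink toward
  the identity (structure-preserving) and subject perturbations shrink
  toward the group matrix by bisection (tolerance 1e-3).
- Infeasible group specs (between target above sqrt of the within product,
  or repair moving an entry by > 0.2) raise immediately.
- Filter: `scipy.signal.sosfiltfilt`; series shorter than 3 x (2 x sections
  + 1) samples are rejected with a minimum-length hint.
- Artifact segments shorter than 8 samples fall back from the smoothing
  spline to a linear trend; fully flagged recordings are cubic-detrended
  with a warning.
- Walking-block indexing: start = floor(t x fs), half-open; 385 samples at
  the defaults.
- Zero-variance channels propagate as NaN with a validity mask rather than
  raising, since single dead channels are routine in real recordings.

## Limitations

- The 5-channels-per-region montage is a stand-in for the unpublished probe
  geometry; analyses depend only on the partition, but channel counts per
  region affect the variance of the aggregated connectivity values.
- The estimand bookkeeping (finite-window correlation bias, PCA distortion)
  is specific to the default chain; changing the band, block length, trial
  count, or PCA depth changes the estimand, and the recorded ground truth
  tracks only the defaults.
- The shared/specific split of between-subject variance (0.77) and the
  Fisher-z latent perturbation SD (0.10) are modelling choices; only their
  combined effect on observed dispersion is constrained by the published
  SDs.
- Deoxygenated haemoglobin is simulated and carried through conversion but
  never analysed, matching the study being reproduced.
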