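# Methods

This note documents the models, numerical conventions and design choices of
`gabagamma`.  Everything quantitative stated here is computed by the test
suite or the analysis drivers; nothing is asserted that the code does not
verify.

## 1. Synthetic cohort model

The generator emulates a ten-subject multimodal study in which each
subject's V1 gamma response properties are coupled to their V1 GABA_A
receptor density.

**Latent structure.**  Per subject, a single occipital density level
`bmax_occ ~ Uniform(18, 42)` (arbitrary concentration units) fills the V1
and occipital-calibration PET voxels; the rest of the brain carries a
background of mean 12 with a ±5% per-subject level offset and an 8% smooth
spatial texture, and the pons carries zero specific binding.  The total V1
density is `bmax_occ × n_V1`.  Gamma peak frequency and amplitude follow

    freq = 65 Hz + coupling_freq · (total − mean_total) + N(0, noise_sd_freq)
    amp  = 1.0   + coupling_amp  · (total − mean_total) + N(0, noise_sd_amp)

with frequency clipped into the configured range (45–85 Hz by default, so
the population spans most of the analyzed gamma band).
`CohortConfig.calibrated(geometry, target_pearson=0.75)` sets the slopes so
the coupled part of the frequency spans 34 Hz (amplitude: 0.8 units) and
the residual SDs so the truth-level Pearson correlation is ≈ ±0.75 — the
regime of the effect sizes this design is meant to detect.  Latency is
N(300, 30) ms, alpha/beta suppression depths Uniform(0.3, 0.7), V1 surface
area N(2000, 250) mm², gray-matter density Uniform(0.55, 0.80).  Cohorts
are bit-reproducible given `(config, seed)`.

**MEG forward simulation.**  One template geometry is shared by all
subjects (no per-subject anatomical warp): a spherical head model with
radial point magnetometers on a helmet cap of radius 10 cm (102 sensors by
default, 24 in the reduced configuration), and a source grid at 6 mm
spacing whose V1 patch is a fixed contiguous 2×2×2 block in the posterior
lobe.  Each trial superposes, at the V1 patch with fixed tangential
orientations:

* a Gaussian-envelope gamma burst (σ_env = 70 ms) at the subject's peak
  frequency, centred at the subject's latency, random phase per trial;
* ongoing 10.5 Hz (alpha) and 20 Hz (beta) rhythms attenuated
  post-stimulus by the subject's suppression depths (Gaussian attenuation
  profiles peaking at 400/350 ms);
* spatially correlated pink noise projected from 30 random interior
  dipoles, plus 2% white sensor noise.

Fields are computed with the Sarvas closed form (radial dipoles are
silent; sources must lie strictly inside the sensor shell).  The noise is
scaled against a **unit-amplitude reference** burst (`snr` = reference
signal RMS / noise RMS, default 4), deliberately not against the subject's
own amplitude, so inter-subject amplitude differences survive into the
recordings.  Blink trials (default rate 0.1) carry a stereotyped ~300 ms
biphasic EOG deflection of 250 µV plus a frontal-dipole field artifact.
Epochs are 600 samples at 600 Hz, −200 to +800 ms.

**PET forward simulation.**  Twelve frames over 55 min under instantaneous
pseudo-equilibrium partial saturation: the free (plus non-specific) ligand
concentration decays as `F(t) = F∞(1 + 2 e^{−t/5 min})` over the early
frames and sits exactly at the plateau `F∞` from 20 min onward (frames
8–12); the bound concentration per voxel is `B = B′max·F/(F + K_d)` with
`F∞ = K_d = 10` by default, and voxel noise is Gaussian with SD 5% of
`F∞`.  The early-frame free-ligand variation is what makes the apparent
K_d identifiable (section 3).

## 2. MEG analysis chain

* **Trial rejection**: trials with peak |EOG| > 150 µV are dropped; if all
  trials are rejected a hard error names the threshold.
* **Morlet CSD**: Gaussian-windowed complex exponentials with
  σ_t = m/(2πf), width m = 7 cycles, truncated at 3σ_t and
  **amplitude-normalized** (a pure sinusoid of amplitude a at the bin
  frequency gives |w| = a, so no 1/f tilt is introduced by the analysis
  itself).  Coefficients are evaluated at the analysis instants only;
  edges are zero-padded, and frequencies whose full 6σ_t support exceeds
  the 1 s epoch (below ≈ 6.7 Hz at m = 7) are flagged invalid rather than
  silently truncated.  The CSD at each (f, t) is the trial average of
  w wᴴ, Hermitian by construction.
* **Grids**: frequencies 4–15 Hz at 0.25 Hz, 15–30 at 0.5, 36–104 at 2
  (the reduced configuration uses 36–104 at 4 Hz only); time instants at
  1/60 s ≈ 16.7 ms steps (ten samples — the conventional "17 ms" bin),
  −200 to +783 ms; the baseline window is half-open [−200, 0) ms.
* **DICS**: real part of the CSD with diagonal loading λ·mean(diag),
  λ = 0.05; per grid point the spatial filter W = (LᵀC⁻¹L)⁻¹LᵀC⁻¹ over two
  tangential orientations satisfies W·L = I exactly; power is the largest
  eigenvalue of the 2×2 oriented-power matrix, hence ≥ 0.  One filter per
  frequency is computed from the time-averaged (baseline + active) CSD by
  default; per-time-bin filters are available via `common_filter=False`
  (which of the two the original event-related variant used is not
  documented; both are provided).
* **Temporal smoothing**: 13-bin moving average (the bin plus six on each
  side); at epoch edges the window shrinks to the available bins rather
  than padding with invented data.
* **Gamma band averaging**: bins ≥ 40 Hz are replaced by the mean over
  centre ± 4 Hz of available bins (40 Hz ← mean of 36–44 Hz); lower bins
  untouched.
* **Normalization**: baseline mean per (point, frequency) subtracted;
  absolute mode divides by the SD over all V1 points × band frequencies ×
  baseline bins, separately for the low (≤ 30 Hz) and high (≥ 40 Hz)
  bands, making the measure invariant to global sensor gain; percent mode
  is 100·(P − baseline)/baseline and errors on zero baseline.  The V1
  response is the mean over V1 grid points.

**Peak extraction** searches the band's frequency range within 0–600 ms
for the signed extremum (gamma: largest increase; alpha/beta: deepest
suppression, reported as a negative amplitude); ties break toward the
lower frequency and earlier instant (logged).  The smoothed,
band-averaged response is used — the same array that feeds the
correlations — with no sub-bin interpolation, since peaks are reported at
grid resolution.  **Group stimulation maps** are per-point paired t-tests
of mean band power, post (0–600 ms) vs pre (−200–0 ms), across subjects at
p < 0.005 uncorrected; points with zero across-subject variance are
excluded as undefined.

## 3. PET analysis chain

The static image is the voxelwise **sum of frames 8–12** (20–55 min);
`bmax_map` divides by the number of summed frames so densities are
reported on the per-frame concentration scale.  The free-ligand
concentration is the mean static pons intensity.

**Scatchard calibration.**  A single pseudo-equilibrium image cannot
identify the apparent K_d: across voxels at a common free concentration F,
the points (B, B/F) are exactly collinear through the origin regardless of
the density field, and (K_d, B′max) trade off perfectly in
`C = F + B′max·F/(F+K_d)`.  The identifying information in a
partial-saturation protocol is the **time course**: as the free
concentration decays across frames, the occipital bound concentration
`B_t = C_t − F_t` (with `F_t` from the pons) moves along the saturation
curve, and the frame trajectory `(B_t, B_t/F_t)` lies on the Scatchard
line with slope −1/K_d.  `fit_scatchard` therefore regresses `B_t/F_t` on
`B_t` across frames; a non-negative slope (no saturation signal) or a
flat trajectory raises a degenerate-fit error.  On noise-free synthetic
data the fit recovers K_d exactly and the full round trip
estimator(simulator(truth)) reproduces the voxelwise B′max field to
relative error < 1e−6.  K_d scales linearly with a global rescaling of
all concentrations (Scatchard scale equivariance).

`B′max(v) = (C(v) − F)(1 + K_d/F)`; negative bound values (noise below
the free level) are clipped to zero and counted.  Maps are smoothed with
a separable Gaussian of FWHM 15 × 15 × 21 mm (reflective boundaries; the
interior mean and the total sum are conserved) **before** V1 aggregation.
The V1 density is the **sum** over the unique set of PET voxels nearest to
the V1 MR voxels (de-duplicated — which is why V1 size is a confound and
is regressed out in the confound-controlled variant); the whole-brain
control uses the same aggregation with an all-brain mask.

## 4. Correlation statistics

Spearman's ρ (average ranks for ties) and Pearson's r with two-sided
p-values from t = r√(n−2)/√(1−r²), df = n−2 — the convention recovered
exactly from the published (r, p) pairs (0.75973 → 0.0108, −0.61411 →
0.0589 at n = 10).  A permutation-based Spearman p is available by flag.
The JZS correlation Bayes factor is the single-regressor
Jeffreys–Zellner–Siow BF evaluated at R² = r²: an expectation of
`(1+g)^{(n−2)/2} (1+(1−r²)g)^{−(n−1)/2}` over an inverse-gamma(½, n/2)
mixing density for Zellner's g, computed by adaptive quadrature (absolute
tolerance 1e−6; non-convergence raises with the achieved error).  It is
symmetric in the sign of r, strictly increasing in |r| and in n, below 1
at r = 0, and matches a 10⁶-sample Monte-Carlo estimate of the same
integral within 1%.  The published values 6.0064 and 1.4159 reproduce to
four decimals.

Bootstrap 95% limits follow the leave-2-out scheme: 200 resamples each
dropping two distinct random subjects, percentile CI (linear
interpolation) of the 200 Spearman values; with 45 distinct pairs and 200
draws, repeats across resamples are expected.  Confound regression is OLS
with intercept on V1 surface area and gray-matter density (the latter
computed as the mean gray-matter fraction over the unique V1-PET voxel
set); residuals replace the raw densities in the "regressed" report rows.
The specificity null draws 100 fully random and 100 contiguous
(seeded region-grown) voxel sets, each of the subject's V1 voxel count and
entirely > 4 cm from V1, and correlates each set's total density with the
MEG feature.  All p-values are uncorrected.

## 5. Problem sizes and verification scales

The repeated-simulation studies run on a reduced configuration chosen as
the package's verification scale: 24 sensors, the V1 patch as the source
grid (the correlation analysis consumes only V1-aggregated responses),
gamma-only frequencies at 4 Hz spacing, 20 trials per subject, and a
22×22×16 PET volume at 6 mm voxels.  The full configuration (200 trials
within the 151–254 accepted range, three-range frequency grid, volumetric
posterior source grid) is used by the analysis drivers and the
single-cohort tests.  Key recovery results at the reduced scale, computed
in the test suite:

* recovered vs truth-level Spearman ρ (gamma frequency and amplitude vs
  V1 density): median absolute error ≤ 0.15 over 200 seeded cohorts, with
  the correct signs;
* zero-coupling cohorts: fraction of p < 0.05 results within the 99%
  binomial interval around 0.05;
* DICS localization of a single gamma source at SNR 3: error ≤ one grid
  spacing (6 mm) in ≥ 95 of 100 runs;
* estimated vs true total V1 B′max across a cohort at 5% PET noise:
  r ≥ 0.99 (smoothed), estimator bias < 2% (unsmoothed V1 mean).

## 6. What the synthetic data do and do not show

The generator provides exact ground truth, controlled coupling and
physically consistent forward models (spherical-conductor magnetics,
saturation-binding PET), so passing tests demonstrate that the estimators
are correct implementations with the claimed statistical behaviour under
the stated noise models.  They do not demonstrate robustness to what real
data add: per-subject head and cortical geometry (one template grid is
shared; the spherical model has no anatomy), gradiometer pickup and
environmental noise spectra, non-Gaussian and motion artifacts beyond the
stereotyped blink, radioligand kinetics beyond instantaneous
pseudo-equilibrium (no plasma input function, no attenuation or
partial-volume effects), or task behaviour.  The amplitude feature passes
through the power domain (squared, peak-picked), so its recovery is
noisier than frequency's; rank-based statistics absorb the monotone
distortion.

## 7. Known limitations and open choices

* The event-related beamformer's original per-time-bin filter behaviour is
  not documented; common-per-frequency filters are the default, the
  alternative is a flag.
* Peak amplitude is read from the smoothed, band-averaged response
  (whether the original used raw bins is unstated).
* The apparent K_d is fitted per subject from the frame trajectory; a
  fixed literature value can be supplied instead by constructing
  `ScatchardFit` directly.
* Bootstrap percentiles use linear interpolation; order-statistic
  percentiles would differ slightly at n = 200.
* Theta (4–7 Hz) is computed by the machinery but has no peak-extraction
  default, matching its null role in the group analysis; at m = 7 the
  lowest analysis frequencies are flagged for wavelet support exceeding
  the epoch.
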