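# Methods

This note documents the models, parameter choices and numerical decisions
behind `smstoich`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Forward model (synthetic movies)

Emitters are point sources at continuous positions on a field; pixel `(i, j)`
spans `[j·px, (j+1)·px) × [i·px, (i+1)·px)` with the origin at the top-left
corner of pixel `(0, 0)`. Each emitter of oligomeric order `n` carries
`k ~ Binomial(n, p)` fluorescent subunits (`p` = labeling/maturation
probability, default 0.70); `k = 0` emitters contribute no signal. The PSF is
an isotropic 2-D Gaussian of width `psf_sigma_nm` (default 150 nm)
*integrated over pixel areas* via error functions, not centre-sampled.

Brightness. Each fluorophore emits an expected `photons_per_fluorophore`
(default 250) detected photoelectrons per 30 ms frame, modulated by a
per-fluorophore log-normal factor of mean 1 and coefficient of variation
`brightness_cv` (default 0.25) that is fixed for the whole movie. This
reproduces two features of real mEGFP data: the monomer brightness
distribution is wider than shot noise alone, and the width of the `k`-mer
brightness distribution grows as `√k` (independent factors add in variance).
The defaults are stand-ins for an unreported photon budget and PSF width;
both are exposed in the configuration. With them a monomer has peak-pixel
SNR ≈ 5–10 over typical backgrounds, i.e. visibly but not comfortably above
noise, which is the regime that stresses the analysis.

Camera. Detected photoelectrons per pixel are Poisson; EM amplification is
modelled as the standard Gamma approximation (shape = photoelectron count,
scale = `em_gain`), divided by the sensitivity, offset by the baseline, plus
Gaussian read noise, rounded and clipped to 16 bits. The default camera is
the single-molecule EMCCD configuration (100 nm pixels, EM gain 65.4
counts/photoelectron, offset 170, QE 0.95); a second preset carries the
cell-imaging conversion set (gain 1, baseline 400, sensitivity 0.46, QE
0.72, 130 nm pixels). The inverse conversion is
`photons = (counts − offset)·sensitivity/em_gain`, divided by QE only when
photon units (rather than photoelectron units) are requested; brightnesses
throughout are photoelectrons by default.

Mobility. Mobile emitters take isotropic Brownian steps of per-axis variance
`2·D·Δt` (default `D` = 0.5 µm²/s, Δt = 30 ms) and reflect at the field
boundary; immobile emitters have `D = 0`.

Default `background_photons` is 0 (offset plus read noise only); the
study-condition scenes used by the benchmarks set 2 photoelectrons/px/frame
of membrane autofluorescence, and the detection stress test uses 5.

What the generator does *not* emulate: photobleaching and blinking, PSF
aberrations and z-dependence, sCMOS pixel-dependent noise, membrane
inhomogeneity, and spot overlap beyond what the configured minimum emitter
separation allows. Benchmarks passing on these movies therefore validate the
*analysis chain* under its stated model, not robustness to every artefact of
real recordings.

## Detection and photometry

Candidates are local maxima of a difference-of-Gaussians response with
scales (0.8, 1.6) × the PSF width, thresholded at 5× the response's robust
(MAD) noise; on a noiseless image any structure above the flat median
counts. Each candidate is fitted over a 7×7 px inner ROI with a
pixel-integrated symmetric Gaussian plus constant, the local background
being the median of the 11×11 px outer annulus. ROIs touching the border,
non-converged fits and non-positive fluxes are rejected.

Brightness is reported from a second, amplitude-only pass in which the
Gaussian width is held at the instrument PSF value (`photometry_sigma_nm`,
default 150 nm) and the centre at the free-fit position. The width of a
diffraction-limited spot is a property of the optics, not of the particle;
re-estimating it per spot at SNR ≈ 5 couples the width and volume errors
into a heavy-tailed brightness distribution (empirically ~40% RMS for
monomers versus ~10–12% photon-limited), which degrades both the monomer
calibration and the mixture decomposition. Setting
`photometry_sigma_nm=None` restores the free-fit volume. Conversion to
photons is applied to the fitted volume, not per pixel, to avoid clamping
bias. The free fit always supplies the reported width.

Filters: same-frame pairs closer than 7 px are both rejected (conservative —
keeps the brightness distribution uncontaminated at the cost of recall);
fitted widths above 200 nm are rejected; a spot is rejected as `multi_peak`
when the lightly smoothed fit residual shows a secondary peak at ≥ 2 px from
the centre that reaches 30% of the fitted peak amplitude *and* clears 5× the
residual's robust noise — the significance gate is essential because shot
noise on a genuine single spot's flanks otherwise produces spurious
"second peaks" in ~25% of SNR-5 spots. Filtering is idempotent on the
accepted set. The `net_gradient` score (inward radial gradient sum over an
odd box, default 7 px) is provided as the alternative detection statistic
used for cell data, with a minimum-net-gradient threshold.

Recall and precision of detection-plus-photometry are ≥ 95% for isolated
SNR ≥ 5 emitters; the quality filters intentionally trade additional recall
for purity (for the dimmest monomers the width filter alone removes ~5–10%,
consistent with the Cramér–Rao width uncertainty at 250 photoelectrons under
EMCCD excess noise).

## Monomer calibration

The calibration sample (surface-captured monomeric construct, analysed
exactly like a sample) is dominated by monomers but can carry a dimer
contamination from purification. `calibrate_monomer` estimates the *mean*
and sd of the monomeric population by maximum likelihood of a two-component
model — `N(μ₁, σ₁)` plus a dimer component constrained at `N(2μ₁, √2σ₁)`
with free weight — initialised at the lowest substantial KDE mode. The mean
(not the mode) is the right location parameter because the single-fluorophore
brightness distribution is right-skewed, while the mixture components sit at
exact integer multiples of μ₁. A zero-variance sample raises a
`CalibrationError` naming the degenerate mean; fewer than 50 particles
(configurable) are rejected.

## Mixture fit and labeling correction

The brightness Pdf is a Gaussian KDE (Silverman bandwidth by default) on a
uniform 2048-point grid covering `[min(0, data_min − 3bw), data_max + 3bw]`,
renormalized to unit trapezoidal integral. Components `n = 1…max_n`
(`max_n` = 30) are unit-area Gaussians with mean `n·μ₁` and sd `√n·σ₁`
(independent-fluorophore variance addition; a linear-sd alternative sits
behind `sd_mode="linear"`), *convolved with the KDE bandwidth*
(`sd = √(n σ₁² + bw²)`) so the fitted curve and the components live on the
same smoothing scale — without this the smoothing bias systematically leaks
weight to higher orders. Weights come from nonnegative least squares against
the density, are renormalized to sum 1, and weights below 10⁻³ are reported
as exact zeros. The fit is invariant under common rescaling of the
brightnesses and (μ₁, σ₁). A fixed-component maximum-likelihood (EM) fit on
the raw brightnesses is available as `objective="mle"` for cross-checking.

Partial labeling: the observed label-count fractions are related to true
subunit fractions by the binomial mixing matrix restricted to detectable
(k ≥ 1) particles. `forward_labeling` implements the forward map and serves
as the in-repo oracle; `correct_labeling` inverts it by NNLS with
renormalization, returning the nearest nonnegative solution (with a warning
carrying the residual) when the observed vector lies outside the feasible
cone, as happens for noisy fits. The correction order is fixed: fit the
observed label-count fractions first, then invert — never the reverse. The
round trip is exact to < 10⁻⁶ on noise-free distributions over `n ≤ 6` at
`p = 0.7`; the inversion necessarily amplifies statistical noise as `p`
decreases.

Particle density is `accepted count / field area` (per analysed frame), with
an optional dilution factor for samples diluted before imaging.

## Tracking and mobility

Localizations are linked per frame by minimum-cost (Hungarian) assignment
with a displacement cap (default 3 px/frame) and gap closing (default 1
frame). A track is **immobile** when it spans ≥ 10 frames and its RMS radial
deviation from its centroid stays within `spread_multiple × precision_px`
("the same localization over time"); it is **mobile** when steps above that
bound persist over ≥ 5 consecutive frames; anything else is unclassified and
excluded from the reported percentages, which always sum to 100 over
classified tracks. The immobile test precedes the mobile test, since pure
localization noise produces occasional above-bound step runs. The default
`precision_px` = 0.25 (25 nm) is the measured per-axis localization spread
of immobile ~250-photoelectron spots under the default imaging conditions;
the multiple 2 is the declared operationalisation of "same localization" —
the numeric displacement bound is a package convention, not a measured
constant. Fast mobile tracks fragment at the displacement cap
(P(step > 3 px) ≈ 0.22 at D = 0.5 µm²/s), so mobile *track counts*
overestimate mobile *particle* counts; classification accuracy is assessed
per track against ground truth. Only the first 100 frames are analysed when
`first_n_frames=100` is set (the default in the pipeline configuration).

## Leakage statistic

`% release = 100·(F_sample − F_onlyLUVs)/(F_Triton − F_onlyLUVs)` per time
point, with the per-well Triton maximum as the 100% anchor and no cross-well
averaging or smoothing. Values outside [0, 100] (possible only through
noise) are reported unclamped with a flag; wells whose Triton maximum does
not exceed the baseline are marked invalid. The LUV batch gate requires a
permeabilized/intact fluorescence ratio ≥ 5. The statistic is invariant
under a common additive shift of all three channels and monotone in
`F_sample`.

## Benchmark problem sizes

The end-to-end recovery benchmark renders a 576×576 px (57.6 µm)² field with
1800 emitters (50/50 dimer/trimer, 70% labeling, 700 nm minimum separation)
for 1500 frames, detects on a single frame (distinct emitters, not repeated
observations, carry the statistical information), and calibrates on a
separately rendered field of 800 monomers — enough that the finite-population
error of the mean single-fluorophore brightness (CV 0.25/√800 ≈ 0.9%) does
not dominate. With ~1530 accepted particles the corrected fractions recover
the ground truth within ±0.05 across seeds (tolerance ±0.07). The detection
benchmark uses 80 isolated monomers over 5 frames on a 5 pe/px background;
the mobility benchmark 40 emitters over 100 frames. These sizes keep the
full validation run to a few minutes on one CPU while leaving the statistical
errors small against the stated tolerances.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded explicitly;
scene generation, rendering and the pipeline derive child seeds
deterministically. The same seed and configuration reproduce byte-identical
movies, localization tables and result JSON.

## Known limitations

- The binomial labeling correction is validated self-consistently against
  its own forward model; the correction used by the original acquisition
  software is unpublished detail.
- Gaussian components only approximate the mildly skewed k-mer brightness
  distributions; at `max_n` approaching the data's dynamic range the
  decomposition of neighbouring high orders becomes ill-conditioned.
- No photobleaching-step counting, temporal intensity traces, multi-emitter
  joint fitting, drift correction, MSD estimation or state-switching
  mobility models.
- Two quantum-efficiency conventions exist in the camera presets (0.95
  detection metadata vs 0.72 photon conversion); brightness units are
  photoelectrons by default and the QE division is opt-in, so the choice is
  explicit in the configuration.
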