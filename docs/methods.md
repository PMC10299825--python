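# Methods

This note documents the models implemented in `pupilbold`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a user auditing results should
know about.

## Signal model

A session is 5 min of simultaneous recording: pupil diameter at 250 Hz
with validity flags, cardiac pulse and respiratory belt traces, six
rigid-body motion parameters per volume, and ROI-average BOLD at
TR = 2 s (150 volumes). The working model for coupling analyses is

    BOLD_roi(t) = T[pupil-linked neural signal](t) + nuisance(t) + ε(t)

where `T` is the neural-to-BOLD transfer under investigation. The three
analyses instantiate `T` three ways: as a double-gamma HRF with swept
time-to-peak, as a pure time shift (lagged cross-correlation), and as an
unconstrained frequency-domain relation (cross-spectral density). The
blind deconvolution inverts the first form per ROI and participant.

## Pupil preprocessing

* Blink interpolation replaces each invalid run, widened by 100 ms before
  onset and 400 ms after offset, with the line through the nearest valid
  flanking samples; runs touching a boundary hold the nearest valid value.
* Sessions whose *raw* trace exceeds 25% invalid samples are excluded
  (strict inequality: exactly 25% is kept).
* The derivative is computed at the native 250 Hz (forward difference ×
  rate, dilation positive) before any resampling, preserving fast
  constriction/dilation structure that TR-level differencing would alias.
* The 1-s backward shift compensates the pupil's physiological lag behind
  the neural activity of the arousal nuclei; it applies to both variants
  and can be set to 0 (`AnalysisConfig.shift_s`) for compatibility with
  no-shift analyses. Ground-truth recovery studies on synthetic data use
  shift 0 because the generator couples BOLD to the pupil signal directly,
  without simulating a pupillomotor delay.
* Resampling averages each TR bin after discarding samples beyond ±3 SD of
  the bin's own mean (the bin's SD, not a global one) and re-averaging the
  survivors; a bin losing every sample falls back to its original mean
  with a warning. Trailing samples beyond `n_volumes · TR` are truncated.

## Nuisance model (33 columns)

Six motion parameters; sin/cos of 1–5× the cardiac and respiratory phase
(10 + 10 columns); six slow regressors; one ventricle column; all columns
demeaned, with a rank check that names collinear columns.

* Cardiac phase is linear between detected pulse peaks (adaptive
  threshold halfway between the median and the 95th percentile, 0.25-s
  refractory period). Respiratory phase is the amplitude-histogram-
  equalised belt signal signed by the smoothed derivative (inhale vs
  exhale), so it is invariant to affine rescaling of the belt.
* Phases are evaluated at each volume's temporal midpoint (TR/2): the
  series are whole-volume ROI averages and no slice timing is modelled.
* Slow-regressor windows: 6 s for heart-rate frequency (1/mean IBI) and
  variability (SD of IBIs), 12 s for respiratory frequency (mean-crossing
  rate), amplitude (max−min excursion) and RVT (excursion × frequency,
  i.e. excursion over breath period). The source protocol lists these
  regressors without estimator details; the window lengths follow the
  conventions of the RETROICOR/RVT literature and are constants in
  `pupilbold.nuisance`, not reproductions of an undocumented original.
* The ventricle regressor is an externally supplied time series (simulated
  here; extracted from a delineated mask on real data).

## First-level GLM

Per session: intercept, `floor(2·n·TR/cutoff)` discrete-cosine drift
columns (cut-off 128 s), the nuisance block and one pupil column; two
sessions form a block-diagonal design and the contrast is the unweighted
mean of per-session pupil betas (sessions have equal length; no weighting
information exists). Pupil regressors are not orthogonalised against the
nuisance block.

AR(1) correction: the lag-1 autocorrelation of the OLS residual is
estimated (Yule–Walker), then corrected by the *design-induced bias*
`−tr(PL)/(n−p)` — the autocorrelation white noise inherits from being
projected off ~40 smooth regressors (measured ≈ −0.09 for this design;
whitening with the uncorrected estimate inflated the empirical type-I
rate from 0.050 to ≈ 0.073). Both y and X are then prewhitened with
`(1, −ρ)` (first row scaled by √(1−ρ²)) and refitted;
`dof = n − rank(X)`. A single global ρ per series is used: the voxelwise
pooling of SPM-style AR corrections has no analog for one ROI average.

## Blind HRF estimation

The cleaned series (nuisance + drift residual, z-scored) is thresholded
at k = 1 SD; each *upward crossing* contributes one delta (one event per
excursion, avoiding collinear adjacent deltas). The pipeline default
additionally counts downward crossings of −k as events of sign −1
(`two_sided`): the underlying neural signal is modelled as symmetric, so
negative excursions are equally informative and doubling the event count
materially stabilises the kernel estimate. The operation-level default of
`detect_pseudo_events` remains positive-only.

The kernel is fitted by OLS as `β₁·canonical + β₂·temporal-derivative +
β₃·dispersion-derivative + c`, with the basis sampled at the TR, and
reconstructed on a 0.1-s grid; **the reported TTP is the argmax of the
reconstructed kernel**. Note the distinction maintained throughout: the
sweep's "TTP" label is the delay parameter p₁ of the double-gamma (the
field's operational convention), while a kernel's actual argmax is
≈ p₁ − 1 for unit dispersion; `HRFKernel.peak_time` always reports the
argmax.

An onset-shift search (`lag_search`) exists for event trains supplied in
neural time, but defaults to no shift: events detected on the BOLD series
itself are already expressed in BOLD time, and an R²-selected shift is not
statistically identified against the temporal derivative, which can absorb
±1 volume of misalignment with large coefficients and make the
reconstructed argmax jump by ±2 s with the noise-driven shift choice.

AR(1) enters this stage only as a recorded diagnostic (`CleanedSeries.
ar1_rho`), not as a whitening filter applied to the series: whitening
before fitting would convolve the target kernel with `(1, −ρ)` and bias
its apparent peak earlier, and OLS point estimates are unbiased under
AR(1) noise anyway.

Concatenation across sessions cleans each session independently, detects
events on the concatenation, and drops onsets within one kernel length
(32 s) of any session boundary so no response model crosses a seam.

Identifiability caveat (measured on synthetic data, documented because it
constrains interpretation): when the ground truth is a *sparse* point
process, threshold-crossing detection adapts to the kernel — crossings
occur a fixed shape-fraction after onset — and absolute TTP information is
largely destroyed; recovered TTPs compress toward the crossing-aligned
rise time. With the band-limited continuous neural signal of the study
generator, between-condition TTP *ordering* (e.g. faster subcortical vs
slower cortical kernels) is reliably recovered, but absolute recovered
values remain compressed. Blind TTPs from this method should therefore be
read comparatively, not as absolute latencies.

## Coupling analyses

* Sweep: kernels with p₁ ∈ {1…6} are sampled directly on the TR grid and
  convolved with the volume-locked pupil regressors (the down-sampled
  series, not the 250-Hz trace); a fine-grid kernel mode exists for
  sensitivity checks. Unit-peak kernel normalisation is cosmetic — t is
  invariant to kernel scale (asserted in tests).
* Cross-correlation: `r(ℓ) = corr(BOLD(t), pupil(t+ℓ))` over the
  *shrinking overlap* (no zero padding, which would bias r toward zero
  asymmetrically across lags); ℓ ∈ {−8…+8} s in TR steps; Fisher z per
  lag; the sign convention string is stored in every result.
* CSD: Welch estimate with a Hann taper, window 10 samples, overlap 3, at
  fs = 0.5 Hz, evaluated on a zero-padded 256-point grid. The padding
  exists because peak frequencies of interest (0.008–0.09 Hz) are finer
  than a 10-sample window's native resolution; zero padding interpolates
  the spectrum without adding resolution, and the transform length is
  exposed (`csd_nfft`) rather than hidden.

## Group statistics

Second-level procedures consume only per-participant summaries (t values,
Fisher z), never concatenated series. FDR families: the set of ROIs for
main-effect tables, lags-within-ROI for cross-correlation bins
(configurable, `fdr_family`). The main effect of TTP is a one-way
repeated-measures ANOVA with participant as the blocking factor —
the minimal test matching a within-subject factor with six levels; it is
cross-checked against an independent implementation (pingouin) in tests.
The `rm_anova_main_effect` F statistic equals the squared paired t for two
levels.

## Synthetic-data generator

What it emulates — and is fixed by the study conditions: 5-min sessions,
TR = 2 s (150 volumes), pupil at 250 Hz, slow pupil fluctuations as
4th-order Butterworth band-passed Gaussian noise in 0.04–0.1 Hz
(standardised; generated forward–backward so no phase distortion), blinks
as a Poisson process (12/min) with uniform 100–400 ms gaps driving the
recorded diameter to a floor, cardiac ≈ 65 bpm with 3% inter-beat jitter
(60 bpm would alias exactly to DC at fs = 0.5 Hz — a degenerate, unrealistic
special case), respiration 18/min (0.3 Hz) with slow amplitude
modulation, BOLD noise SD 0.5 relative to the unit-variance neural
signal, and a physiological "bleed" of aliased cardiac/respiratory
sinusoids phase-locked to the simulated traces so the RETROICOR columns
have a real target.

Coupling transfer: `mode="lag"` (BOLD = gain · pupil(t−lag), lag a TR
multiple; leading samples hold the first value, which the shrinking-
overlap correlation excludes, so noise-free recovery of −lag is exact),
`mode="hrf"` (convolution with a double-gamma of configurable p₁), or
`mode="none"`. A separate point-process generator
(`simulate_point_process_bold`) provides sparse ground-truth event trains
for the deconvolution path.

What it does **not** emulate: image space (ROI series are simulated
directly), gaze position, pupil foreshortening artifacts, scanner drifts
beyond what the DCT basis absorbs, motion-correlated signal (motion
parameters are independent random walks), non-Gaussian BOLD noise, and
any true pupillomotor delay. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every artifact of real data.

## Validation scales

The acceptance script runs the recovery studies at the scale of the
design they validate: 100 lag-recovery studies of 20 participants × 2
sessions, 12 TTP-sweep runs of 20 participants, a 20-participant blind-
deconvolution ordering study, ≥ 2000-replicate calibration nulls. The
pytest suite runs trimmed versions of the same checks (e.g. 21 lag
studies of 12 participants) so the default test run stays fast; the
thresholds asserted are identical.

## Known limitations

* The AR(1) bias correction is exact under white noise and first-order
  under genuinely AR noise; strongly autocorrelated noise with a small
  sample still yields mild anticonservatism (measured ≈ 6.5% at ρ = 0.4,
  n = 150).
* Blind HRF TTPs are comparative, not absolute (see above).
* The CSD's reported peak frequency inherits Welch bias from the very
  short (10-sample) window; with 150-volume sessions the band below
  ~0.05 Hz is estimated from few effective segments.
* `rvt` uses a windowed excursion × frequency estimator rather than
  per-breath interpolation; the two agree for quasi-periodic breathing.
* No scrubbing, no slice-wise physiological correction, no voxelwise
  analyses: the package operates on ROI averages throughout.
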