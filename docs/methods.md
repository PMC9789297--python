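# Methods

## Scope and model

`abrlab` analyses frequency-specific contributions to the auditory
brainstem response (ABR) isolated with the derived-band
(highpass-masking) technique, and fits the cochlear dispersion of their
latencies.  The central quantity is the exponential group-delay law

    t_g(f) = K · f^(−D)        [t_g in ms, f in kHz]

with `K` the delay at 1 kHz and `D` the decay exponent.  The canonical
wave-V-optimised chirp constants, K = 4.54 ms and D = 0.436, are
shipped as `abrlab.dispersion.CE_CHIRP` and double as the default
generative dispersion of the simulator and the starting point of the
model optimiser.

The latency model (`abrlab.model.LatencyDispersionModel`) is a
nonlinear mixed model: latency = A + K·f^(−D) + subject intercept +
residual, with any of A, K, D stratified by two-level factors (wave,
sex, stimulus, spectral profile; effect-coded ±1/2 so coefficients are
contrasts and intercepts cross-stratum means).  The band frequency `f`
is the band's upper edge frequency, with the open-ended top band
assigned one octave above its lower edge (16 kHz for an 8-kHz cutoff).
The marginal Gaussian likelihood is profiled per subject through the
rank-one structure of the random intercept (Sherman–Morrison), so a fit
involves only the fixed effects and two log-SD parameters.  Because the
(K, D) surface is mildly nonconvex, fitting uses multi-start L-BFGS
from the canonical constants plus deterministic perturbations.
Standard errors come from the inverse observed information (numerical
Hessian); confidence intervals are Wald.  Model comparison reports both
the χ² likelihood-ratio test and a BIC Bayes factor,
BF01 = exp((BIC_alt − BIC_null)/2), in whichever direction exceeds 1.

## Stimulus synthesis

Stimuli are sums of sinusoids at integer multiples of 10 Hz between
0.25 and 8 kHz (all configurable), with spectral edges rounded by
quarter-sine/-cosine ramps one ERB_N wide
(ERB_N(f) = 24.7·(4.37·f_kHz + 1) Hz).  The pink profile scales energy
density as 1/f.  Clicks align all components in cosine phase at a
reference time; chirps advance the energy at frequency f by t_g(f).

Two chirp phase constructions are provided.  The default integrates the
delay law into the phase (φ(f) = −2π∫(t_ref − t_g) df), which makes the
stimulus's stationary-phase group delay — the time at which a
narrowband slice around f actually peaks — equal to −t_g(f) relative to
the click.  The literal per-component construction (each sinusoid
shifted by t_g(f)) is also available; for a power law it yields a
measured group delay of (1−D)·t_g and therefore undercompensates the
dispersion it encodes.  The phase-integral form is the default because
the package's simulator, and the premise of dispersion compensation,
assume the response at band f is advanced by t_g(f); the per-component
mode exists for comparison.  Both constructions are phase-only, so
click/chirp pairs have identical magnitude spectra and identical energy
to machine precision; stimuli are normalised to unit energy with the
scale factor stored in metadata (absolute SPL calibration is out of
scope).

Masking noise is built directly in the discrete frequency domain
(profile-shaped magnitudes, uniform random phases, zero below the
cutoff), giving an exact brick-wall edge and an endpoint-periodic
10.5-s buffer suitable for cyclic playback.

## Synthetic cohorts

The simulator emulates the statistical structure the analysis assumes,
not cochlear biophysics.  Each band contributes a one-cycle-sine
deflection per wave; latency = A_w + t_g(f; dispersion) − (chirp
advance) + subject intercept + (wave-V sex offset); amplitude =
band amplitude × subject scalar (× an optional per-band chirp
attenuation emulating on-/off-frequency desynchronization).  Highpass
masking at cutoff c sums the bands with upper edge ≤ c; epochs add
white Gaussian noise.

Defaults mirror the emulated acquisition: 26 F / 18 M subjects,
cutoffs 0.5–8 kHz in octave steps plus broadband, white and pink
click/chirp stimuli, 45-ms epochs with a 5-ms pre-stimulus baseline at
16.384 kHz, 6000 sweeps per condition, stimuli generated at 50 kHz.
Values the study design does not pin down were chosen once as realistic
for adult supra-threshold ABRs and are exposed in `SimCohortSpec`:

- wave templates: wave I base latency 1.0 ms, period 1 ms; wave V
  4.5 ms, period 2 ms (wave V later, slower and larger).  These put the
  broadband wave-I/wave-V peaks near 2.4/5.9 ms.
- per-band amplitudes: wave I weighted toward basal bands (0.10 → 0.40
  a.u.), wave V flatter and ~1.5× larger — wave I is known to draw
  relatively more on high-frequency regions.
- between-subject latency SD 0.3 ms; log-amplitude SD 0.3; wave-V sex
  offset +0.2 ms for males; single-trial noise SD 5 a.u. (≈ 0.065 a.u.
  residual after 6000-sweep averaging, a realistic fraction of the
  largest deflections).
- dispersion differences between waves and sexes default to zero (a
  null-true cohort); mappings of (wave, sex) → (K, D) impose effects
  for power studies.

The generator reproduces the paradigm's additive band structure
exactly (the telescoping identity holds to machine precision) but does
not model travelling-wave mechanics, middle-ear filtering, stimulus
artifacts, non-Gaussian or correlated EEG noise, or within-band
latency dispersion.  Tests passing on these cohorts therefore validate
the *analysis chain* — isolation, alignment, picking, model recovery —
not the physiological realism of any particular waveform.

## Preprocessing

Epochs are band-limited with 4th-order Butterworth filters (100- or
150-Hz highpass; 2-kHz lowpass), applied forward-backward by default so
that peak latencies are unbiased; a causal mode exists and the choice is
recorded in output metadata because it shifts absolute latencies.
Baselines (−5–0 ms mean) are subtracted per epoch.  Averaging groups
epochs into blocks of 250 and weights block means by inverse noise
variance, estimated from the across-trial variance at a single
pre-stimulus sample; with homogeneous noise this reduces to the
arithmetic mean.  The 150-Hz variant (favouring wave I) and the 100-Hz
variant (favouring wave V) are cross-spliced with a 2-ms linear
crossfade centred on 5 ms: pure 150-Hz below 4 ms, pure 100-Hz above
6 ms, complementary weights between.

## Derived bands and stacking

Derived band j is the difference of the averaged responses at
successive cutoffs; the lowest band is the lowest-cutoff response
itself and the top band is broadband minus the highest cutoff, so the
bands sum to broadband identically.  Bands are labelled by the
geometric mean of their edges, treating edge bands as one octave wide
(0.4, 0.7, 1.4, 2.8, 5.7, 11.3 kHz for cutoffs 0.5–8 kHz).

Stacking shifts each band by (reference − band latency) and sums.  The
default reference is the across-band mean of the supplied latencies;
within a cohort comparison all subjects and stacking modes share one
reference so pointwise statistics see a common time base.  Sub-sample
shifts use FFT phase shifts on zero-padded copies (a nearest-sample
mode exists).  Wave-specific stacks are cross-spliced (wave-I stack
early, wave-V stack late).  The "effective mean" — pointwise mean over
subjects divided by pointwise SD — is the SNR-like figure on which
individual-latency compensation shows its benefit.

## Curve registration and automatic picking

Individual responses are aligned by monotone piecewise-linear time
warps (default 10 interior knots) fixed to the identity at the window
ends (default window 0–12 ms).  Warps minimise the penalized squared
difference of derivatives between the warped response and the current
target; the misfit is normalised by the target's mean squared
derivative so the roughness weight λ (default 0.05, chosen by a small
grid on simulated shifted templates) is scale-free.  A slope floor of
0.05 keeps warps strictly monotone.  The target starts at the
cross-sectional average and is refreshed with the mean of the warped
responses ("average-target" iteration).  Because the derivative
criterion has local minima when deflections are displaced by more than
their width, the criterion is evaluated coarse-to-fine: both target and
responses are Gaussian-smoothed with an SD that starts at 1 ms and
halves per iteration; the structural average itself is always built
from raw data and convergence is declared only once the schedule has
reached the raw signals.

Peaks and troughs are picked once, on the structural average, as the
largest interior local maximum in a broad wave window and the deepest
subsequent interior local minimum (earliest wins on exact ties; a
window without a local extremum yields a flagged missing pick).
Individual latencies are the picks mapped back through each response's
inverse warp.  Responses whose post-registration residual power exceeds
the target power are flagged as too noisy to trust.  Pairwise waveform
comparisons (`align_pair`) warp both inputs to their joint mean before
pointwise tests, so latency differences are not mistaken for amplitude
differences.

In the pipeline, latencies are extracted per masking condition
(highpass-masked latencies as proxies for derived-band latencies, the
robust choice at realistic SNR) or per derived band
(`latency_source="derived"`); the noise-free oracle uses the derived
bands because subtraction isolates each band exactly, whereas in a
masked response the tail of the neighbouring band biases the summed
waveform's peak by up to a few tenths of a millisecond.  Pick windows
are centred on the design-prior latencies (chirp constants plus nominal
wave offsets), ±1.5 ms.

For the chirp-benefit analysis, click- and chirp-evoked band responses
are compared after alignment; the chirp responses are first shifted
back by the known stimulus advance t_g(f_band) — a pure time shift that
cannot change an aggregate amplitude — so that registration only has to
absorb jitter-scale offsets.  Aggregate amplitudes integrate |x(t)|
over 2–5 ms (wave I), 5–9 ms (wave V) or 2–9 ms (both); benefit is the
chirp-minus-click aggregate as a percentage of click.  Uncertainty on
cohort summaries is the SD over 5000 subject-level bootstrap resamples.

## Permutation and power statistics

Waveform differences are tested with one-sample t_max permutation
tests: pointwise t-scores, a null built from 5000 random whole-subject
sign flips, and family-wise control by referring each |t| to the
permutation distribution of the maximum |t| over the 0–12 ms window.
Sign flips leave the per-point sum of squares unchanged, so the
permuted t-scores are computed from the flipped sums alone — the
calibration study (1000 null simulations × 5000 permutations) runs in
seconds.  Zero-variance time points get t = 0.

Two-sample t-test power uses the noncentral-t distribution with
noncentrality d·√(n1·n2/(n1+n2)) by default; a normal-approximation
mode is provided because published power figures are often computed
that way and run 1–2 percentage points higher at these sample sizes.
The anatomical effect size d = 3.36/6.86 treats the 3.36 % sex
difference in cochlear length against a 6.86 % inter-individual
SD-like dispersion figure, both on the percent scale.

Residual heteroscedasticity across factor levels is tested with
Levene's test; when significant, observations are reweighted by inverse
level variance (normalised to mean 1) and the model refitted with those
precision weights.

## Problem sizes

Simulated studies used by the tests and the reproduction script are
deliberately compact: recovery studies use 20-subject cohorts at the
latency level (240 observations per fit, 100 replicates), registration
tests use 2–12 responses, the end-to-end oracle 6 subjects × 6 masking
conditions, and t_max calibration 16 subjects × 20 time points.  These
sizes give stable Monte-Carlo estimates of the properties checked
(coverage, family-wise error, ≤1-sample latency recovery) while keeping
a full run on one CPU in minutes.

## Known limitations

- The registration criterion aligns on derivatives; with n_knots ≈ 10
  it cannot represent very sharp local time distortions, and alignment
  of waveforms whose latency offsets exceed the coarse smoothing scale
  (~2 ms after the schedule's first step) needs a prior shift, as done
  for the chirp-benefit comparison.
- Wald confidence intervals for (K, D) rely on the quadratic
  approximation at the optimum; at very low SNR profile-likelihood
  intervals would be more faithful.
- The Bayes factor is the BIC approximation, inheriting its unit-
  information prior; it is reported alongside, never instead of, the
  likelihood-ratio test.
- The simulator's noise is white by default; EEG noise is coloured, so
  absolute SNR figures do not transfer to real recordings (a 1/f option
  can be layered on by filtering the epoch noise externally).
- `power_two_sample` assumes equal variances across groups (the
  noncentral-t formula); the unequal-variance generalisation is not
  implemented.
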