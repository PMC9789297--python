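# abrlab — derived-band auditory brainstem response analysis

`abrlab` is a toolkit for studying **cochlear dispersion** with
auditory brainstem responses (ABRs).  The travelling wave in the
cochlea reaches apical (low-frequency) places several milliseconds
after basal (high-frequency) ones, so the frequency-specific
contributions to a click-evoked ABR are desynchronized and the
broadband waves — the auditory-nerve wave I and the brainstem wave V —
are smaller than the sum of their parts.  Rising *chirp* stimuli
compensate this delay; the *derived-band* (highpass-masking) technique
measures it, band by band.

The package implements the full analysis chain around this problem for
researchers in auditory electrophysiology:

- **Stimulus synthesis** (`abrlab.stimulus`): energy-matched click and
  CE-style chirp stimuli (white or 1/f "pink" spectral profiles) built
  from 10-Hz-spaced sinusoids with ERB-wide spectral edge ramps, and
  brick-wall highpass masking-noise buffers.
- **Cohort simulation** (`abrlab.simulate`): synthetic epoched ABR
  recordings for every subject × stimulus × masking condition, with
  known dispersion structure, per-subject random latency intercepts, a
  sex-specific wave-V offset and additive epoch noise.
- **Preprocessing** (`abrlab.preprocess`): 4th-order Butterworth band
  limiting (100/150 Hz highpass variants, 2 kHz lowpass), Bayesian
  (inverse-noise-variance) weighted averaging, and 100/150-Hz
  cross-splicing.
- **Derived-band algebra** (`abrlab.bands`): band isolation by
  subtraction of successive highpass-masked responses (telescoping
  exactly to broadband) and *stacked ABRs* — bands time-shifted to a
  common latency and summed.
- **Curve registration** (`abrlab.registration`): monotone time warping
  to a structural average (average-target scheme, penalized squared
  difference of derivatives), automated peak/trough picking, and
  inverse-warp mapping of picks to individual latencies.
- **Dispersion model and statistics** (`abrlab.model`,
  `abrlab.stats`): the core mixed-effects model, BIC Bayes factors,
  t_max sign-flip permutation tests, aggregate absolute amplitudes,
  subject-level bootstrap, heteroscedasticity reweighting, and
  two-sample t-test power.

## The model

Each observed latency of wave *w* in derived band of frequency *f*
(kHz) for subject *i* is modelled as

    latency = A + K · f^(−D) + b_i + e,    b_i ~ N(0, τ²),  e ~ N(0, σ²)

where `A` (ms) is a constant neural offset, `K` (ms, the group delay at
1 kHz) and `D` (dimensionless) are the cochlear dispersion constants —
the same exponential law `t_g = K·f^(−D)` used to build the chirp — and
`b_i` is a per-subject random intercept.  Any of `A`, `K`, `D` may be
stratified by two-level factors (wave, sex, stimulus, spectral
profile); factors are effect-coded so the coefficients are contrasts
(e.g. `K[wave]` = K_I − K_V).  Estimation is by maximum likelihood with
the subject-level likelihood profiled in closed form; nested fits are
compared with χ² likelihood-ratio tests and BIC Bayes factors.

## Worked example

```python
from abrlab import CE_CHIRP, group_delay
from abrlab.simulate import SimCohortSpec, simulate_latency_table
from abrlab.model import LatencyDispersionModel
from abrlab.stats import power_two_sample

# the chirp's group-delay law: 4.54 ms at 1 kHz, 1.83 ms at 8 kHz
print(group_delay(1.0, CE_CHIRP), group_delay(8.0, CE_CHIRP))

# simulate click-evoked derived-band latencies for 20 subjects and
# refit the dispersion law with a subject random intercept
spec = SimCohortSpec(n_F=10, n_M=10, u_lat_sd=0.2, sex_waveV_offset=0.0,
                     stimuli=(("click", "white"),), seed=1)
table = simulate_latency_table(spec, lat_noise_sd=0.1, seed=2)
fit = LatencyDispersionModel(table, strata={"A": ["wave"]}).fit()
print(fit.summary())

# power of a two-sample t-test for a 3.36 % dispersion difference
# against 6.86 % inter-individual variability, n = 26 vs 18
print(round(100 * power_two_sample(3.36, 6.86, 26, 18), 1))
```

prints

```
4.54 1.8336169651738103
Latency dispersion mixed model (ML)
================================================================
observations: 240   subjects: 20   params: 6
logLik: 173.358   AIC: -334.72   BIC: -313.83
random-intercept SD: 0.1698 ms   residual SD: 0.1014 ms
----------------------------------------------------------------
parameter           estimate        se      [0.025    0.975]
A[const]              2.8536    0.0704      2.7156    2.9916
A[wave]              -3.4975    0.0131     -3.5231   -3.4718
K[const]              4.4793    0.0654      4.3512    4.6075
D[const]              0.4480    0.0085      0.4313    0.4647
log_re_sd            -1.7731    0.1628     -2.0923   -1.4540
log_resid_sd         -2.2890    0.0477     -2.3824   -2.1956
================================================================
34.5
```

The generative constants (K = 4.54, D = 0.436, A_I = 1.0, A_V = 4.5 →
`A[const]` = 2.75 midpoint, `A[wave]` = −3.5 contrast) fall inside the
95 % confidence intervals; the 34.5 % is the power of the cohort's
sex-difference comparison at the anatomical effect size d = 3.36/6.86.

A full simulated study — preprocessing, derived bands, registration,
stacking, model comparison, permutation tests — runs from a YAML config:

```bash
abrlab run config.yaml --outdir out/
abrlab stimulus --kind chirp --profile pink --K 4.54 --D 0.436 -o chirp.wav
abrlab noise --cutoff 2 --profile white -o hp2k.wav
abrlab power --diff 3.36 --sd 6.86 --n1 12 --n2 12
```

## Documentation

`docs/methods.md` describes the model, the synthetic-data generator and
its defaults, the registration procedure, numerical choices and known
limitations.
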