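# Methods

This note documents the generative model behind the synthetic cohorts, the
preprocessing conventions, the statistical procedures, and the numerical
choices the package makes where the underlying study protocol leaves the
design open.

## 1. Study design being emulated

A two-group cross-sectional LDAEP study in healthy women: 30 current
hormonal-contraceptive (HC) users versus 24 non-users (17 past users + 7
never-users, merged because past and never users are indistinguishable on
the outcome and the never-user subgroup alone is too small to carry a
three-group analysis). The outcome is the per-subject LDAEP slope at Cz for
the N1, P2 and N1P2 components; the primary contrast is users vs.
non-users, unadjusted (one-way ANOVA) and adjusted for age and BDI-II
cognitive and somatic-affective subscale scores (ANCOVA).

## 2. Generative model

### Stimulus schedule

Five tone intensities {55, 65, 75, 85, 95} dB SPL, each presented 80 times.
"Pseudo-randomized order" is operationalized as independent uniform
shuffles within consecutive blocks containing one trial per intensity,
which balances intensities over time. Onset-to-onset gaps are uniform on
[1200, 1800] ms (tone duration, 30 ms, is metadata only and does not enter
the scheduling). Onsets are quantized to the 512 Hz analysis grid so that
stimulus-locked samples are well defined after resampling; the quantization
step (≈2 ms) is far below any latency of interest.

### ERP model

Each stimulus adds to every EEG channel a stereotyped response

    s(t) = A_N1 · k(t − t_N1) + A_P2 · k(t − t_P2)

scaled by a fixed spatial topography with weight exactly 1 at Cz and zero
mean across EEG channels — the zero-mean constraint makes the topography
consistent with an average-referenced source pattern, so re-referencing
leaves the Cz response invariant. Amplitudes follow the linear intensity
model centred at 75 dB:

    A_N1(dB) = n1_intercept + n1_slope · (dB − 75)   (negative, ≈ −4 μV at 75 dB)
    A_P2(dB) = p2_intercept + p2_slope · (dB − 75)   (positive, ≈ +4.5 μV at 75 dB)

Centring does not affect the slope and makes the intercept the component
amplitude at the middle intensity.

The default kernel `k` is a unit-peak discrete prolate spheroidal (DPSS,
Slepian) window of half-width 70 ms with time–half-bandwidth 3.5: it is
strictly zero outside its support and maximally concentrated below ≈26 Hz.
This choice makes the kernel an effective fixed point of the linear
processing chain — the 30 Hz low-pass, the FFT resampling and the baseline
correction transmit its peak essentially unchanged (relative error < 1e-5)
— so noiseless ground-truth recovery is exact to numerical precision rather
than approximate. Peak latencies are 51/512 s ≈ 99.6 ms (N1) and 92/512 s ≈
179.7 ms (P2): mid-window for the detection windows below and exactly on
the 512 Hz sample grid, so sample-resolution peak picking incurs no
off-grid bias. A Gaussian kernel (σ = 15/25 ms) is available via
`kernel="gaussian"` for sensitivity analyses; with it, recovery is limited
to ~1e-3 μV/dB by low-pass attenuation and off-grid sampling.

The two kernels' supports ([30, 170] ms and [110, 250] ms) exclude each
other's peak latency and the pre-stimulus baseline window, so component
cross-talk and baseline contamination are exactly zero by construction.

### Group distributions

True component slopes are drawn per group (μV/dB):

|            | N1              | P2              |
| ---        | ---             | ---             |
| HC users   | N(−0.080, 0.033) | N(0.120, 0.068) |
| non-users  | N(−0.052, 0.040) | N(0.084, 0.046) |

The N1P2 slope is not drawn: it is the exact identity P2 − N1, with N1 and
P2 slope deviations treated as independent (a modelling choice; the
implied N1P2 spread, ≈0.076 for users, is close to the target group
summaries, which show ≈0.084 — the data behind those summaries presumably
have mildly correlated components). Slopes are not truncated at zero: a
non-user drawn from N(−0.052, 0.040) has ≈10% probability of a positive N1
slope, and truncation would bias the group means the cohort is supposed to
reproduce. Component polarity is nevertheless guaranteed because the
intercepts dominate (|intercept| ≥ 1 μV ≫ 20 dB · |slope|).

Intercepts are N(−4, 1) (N1, clipped ≤ −1 μV) and N(4.5, 1.2) (P2, clipped
≥ 1 μV) — typical Cz amplitudes for supra-threshold tones. Ages follow the
reported group means/SDs, clipped to the 18–40 inclusion range. BDI-II
subscale scores are negative-binomial (gamma–Poisson, mean 5, size 2.5):
right-skewed, overdispersed, non-negative integers, which is why the
group contrasts on them use rank tests. Subjects flagged for adverse mood
effects (prevalence 11/30 in current users, 14/17 in past users) receive a
+2-point shift on the somatic-affective subscale, ≈0.5 subscale SD — a
medium effect.

### Noise model

* **Background activity**: 1/f-shaped ("pink") Gaussian noise, flat below
  1 Hz, with default RMS 6 μV per channel. Independent pink sources are
  mixed across channels with a Gaussian index-distance kernel
  (scale 1.5 channels), emulating the smooth inter-channel correlation that
  volume conduction produces — without it, simulated channels would be
  mutually uncorrelated and any correlation-based channel screen would
  reject everything. The 6 μV default was calibrated a priori so that the
  single-subject slope standard error at 80 trials (≈0.015 μV/dB) stays
  well below the between-subject slope SDs above: measurement error must
  not dominate the between-subject variance for the group contrast to be
  as reliable as reported.
* **Line noise**: a 50 Hz sinusoid (default 5 μV) with common phase across
  EEG channels.
* **Blinks**: Poisson-scheduled (default 0.15 Hz) biphasic transients
  (~400 ms, ≥100 μV on EOG channels, frontally weighted on EEG). EEG
  contamination is an exact linear mixture of the blink trace, which is the
  regime the EOG-regression cleaner is designed for.
* **Injectables**: flat or high-variance channels, and broadband 100 μV
  burst segments, for exercising the artifact screens.

The default montage is 8 EEG (10-20 subset including Cz) + 2 EOG channels,
chosen for simulation speed; a 64+4 BioSemi-style montage is available via
`montage="biosemi64"`.

What the generator does **not** emulate: realistic head geometry or
leadfields (the topography is a fixed abstract pattern), non-stationary
alpha/mu rhythms, muscle artifact, electrode drift, latency jitter of the
ERP components, or amplitude saturation/habituation across trials.
Passing recovery tests therefore demonstrate correctness of the signal
processing under the stated model, not robustness to every failure mode of
real recordings.

## 3. Preprocessing conventions

Stage order: FFT resampling to 512 Hz → bad-channel detection on a
detection copy → exclusion and re-reference to the average of the remaining
EEG channels → bad-segment detection on a second detection copy → EOG
regression → 30 Hz low-pass → 600 ms epochs with baseline correction →
FASTER-style epoch rejection. Filters for the analysis path are zero-phase
spectral (FFT) filters with raised-cosine transitions and exactly unit
passband gain (low-pass passband edge at the nominal cutoff, 4 Hz
transition), which transmits band-limited signal content bit-faithfully.

* **Detection copies.** The 1 Hz high-pass + line-noise suppression (for
  bad channels) and the 1–100 Hz band-pass + line suppression (for bad
  segments) are applied to copies used only for detection; the analysis
  path itself is never high-passed (the acquisition high-pass is an
  acquisition property, and a 1 Hz high-pass would attenuate genuine
  low-frequency ERP energy). The 30 Hz low-pass suppresses 50 Hz line
  noise on the analysis path by construction.
* **Bad channels** are detected on the *unreferenced* detection copy:
  after an average reference a flat channel carries minus-the-average of
  the others and becomes undetectable, noticeably so on small montages.
  Because the pipeline re-references to the remaining channels after
  exclusion, and re-referencing to all channels followed by re-referencing
  to a subset equals re-referencing to the subset directly, the analysis
  path is unaffected by this ordering. Criteria: |robust z| of
  log-variance > 5; median across 5-s windows of max inter-channel |r| <
  0.4; robust z of >40 Hz relative power > 5. The windowed-median
  correlation makes the screen robust to a single broadband burst, and the
  robust-z scale is floored (1e-3 log units / 1e-4 relative power) so that
  spreads at numerical-precision level in degenerate noise-free inputs do
  not flag outliers. The ICA-based channel-noise criterion of the original
  toolchain is intentionally not reproduced.
* **Bad segments**: consecutive 5-s blocks (trailing partial block
  included) are dropped iff strictly more than 25% of channels have a
  sample SD strictly above 25 μV. Rather than excising samples, epochs
  overlapping a dropped block are discarded, which keeps event bookkeeping
  exact (kept + dropped = scheduled, per intensity).
* **Ocular artifacts**: whole-recording least-squares regression of each
  EEG channel on the raw EOG channels (no intercept; zero EOG therefore
  implies a no-op). This replaces the SOBI + ICLabel ICA route of the
  original toolchain with a method that has the same contract — removal of
  the EOG-correlated subspace — and is exactly testable. ERP signal
  uncorrelated with EOG is preserved in expectation; the chance-correlation
  leakage scales as 1/√n_samples.
* **Epochs**: −100 to +500 ms, sample indices [round(−0.1·fs),
  round(0.5·fs)) relative to the onset sample (307 samples at 512 Hz,
  onset at index 51), baseline-corrected by the pre-stimulus mean (the
  protocol defines the pre-stimulus interval but does not state baseline
  correction; it is standard ERP practice and switchable off).
* **Epoch rejection** mirrors FASTER's default: three per-epoch metrics
  (amplitude range, variance, channel-mean deviation, each averaged over
  channels), dropping epochs with any |z| > 3 across epochs. Under the
  default noise model this removes ≈5% of epochs (≈76 kept of 80 per
  intensity), matching what clean empirical recordings show.

## 4. LDAEP extraction

Per subject and intensity, kept epochs are averaged at Cz (configurable).
N1 is the most negative sample in the inclusive 60–140 ms window, P2 the
most positive in 150–250 ms; ties resolve to the earliest latency, and
latency is reported at sample resolution. N1P2 = P2 − N1 per intensity.
Slopes are OLS fits of amplitude on physical intensity (55…95 dB SPL, not
ranks), so slopes are in μV/dB over the 40 dB span; because OLS is linear
in the response, n1p2_slope = p2_slope − n1_slope holds exactly. An
extremum (not local-peak) definition is used since the manual peak
confirmation of a human scorer cannot be automated; on waveforms with no
true peak inside the window the extremum sits at the window edge, which is
flagged by the tie rule but not otherwise resolved.

## 5. Statistics

* **Normality screen**: Kolmogorov–Smirnov against a normal with estimated
  parameters, i.e. the Lilliefors variant (the plain KS p-value would be
  anti-conservative with estimated parameters).
* **ANOVA**: classical between/within decomposition; for two groups the
  pooled-variance mean difference with a 95% t interval is attached, and
  F = t² exactly. Partial η² = F·df1/(F·df1 + df2). The η² interval is the
  one-sided 95% construction — lower bound from inverting the noncentral-F
  distribution at the observed F, upper bound reported as 1.00 — matching
  the common reporting convention for effect-size CIs printed with an upper
  bound of 1.
* **ANCOVA**: OLS with Type-II sums of squares (per term, the SSE increase
  from dropping that term while retaining all others), F against the
  full-model residual mean square, partial η² = SS_term/(SS_term +
  SS_resid). Estimated marginal means are fitted group values at the
  covariate sample means with SEs from the coefficient covariance; VIFs
  come from auxiliary regressions. Implementation rests on statsmodels;
  the test suite checks it against an independent brute-force
  model-comparison refit.
* **Rank and exact tests**: Wilcoxon rank-sum reported as the Mann–Whitney
  U of the first sample (the convention of R's `wilcox.test`), exact for
  small untied samples, tie-corrected normal approximation otherwise;
  Pearson χ² without continuity correction; Fisher's exact test for 2×2
  tables (larger tables use χ², since exact r×c enumeration is not needed
  for the designs at hand). No multiple-testing correction is applied —
  each test is reported at two-tailed α = 0.05, mirroring the analysis
  plan being emulated.
* **Power**: exact noncentral-t power of the pooled two-sample t-test
  (`scipy.stats.nct`), with the smallest-n search for a target power.
  Validated by self-consistency (bracketing) and Monte Carlo rather than
  against any published required-n figure, because published G*Power
  results depend on unstated tail/allocation settings.

`run_group_analysis` executes the full plan in order — group merge,
per-slope ANOVA and ANCOVA, BDI rank contrasts, BDI-threshold-stratified
t-tests, menstrual-phase ANOVAs within groups, HC-type t-tests, and
adverse-mood contrasts — emitting one tidy table per analysis and explicit
notices for analyses whose design is degenerate in the given cohort.

## 6. Validation studies and problem sizes

`ldaep_lab.experiments` packages the standing validation studies; the test
suite and `scripts/acceptance.py` run them at these sizes:

* **Noiseless recovery**: 4 subjects, 8 trials/intensity (recovery error is
  independent of trial count without noise). Max |slope error| is ~5e-7
  μV/dB with zero channels/segments/epochs excluded.
* **Noisy recovery**: 20 subjects, 80 trials/intensity, default noise, on
  the 8+2 montage; mean absolute slope error ≈0.010 μV/dB, versus ≈0.022
  at 10 trials/intensity — the ~√8 improvement expected from averaging.
* **Type-I error**: 1000 null cohorts (both groups drawn from the non-user
  slope distribution), statistics run on true slopes; rejection at α=0.05
  lands in [0.03, 0.07].
* **Power consistency**: 40 000 simulated cohorts at the two printed N1
  distributions (pooled d ≈ 0.77, n = 30/24) against the noncentral-t
  power (≈0.79); agreement within 0.005 despite the mild group
  heteroscedasticity the analytic formula ignores.

## 7. File formats

Raw recordings are written as 16-bit EDF (hand-written writer, since no
installed library exports EDF; read back via MNE's reader, which serves as
an independent implementation in the round-trip tests) with BIDS-style
events/channels TSV sidecars; quantization error is bounded by the
per-channel physical range divided by 65535 (≈0.003 μV at typical ranges).
Cleaned epochs are stored as `.npy` + JSON sidecar. Ground-truth parameters
are written to a separate CSV that no pipeline stage reads.

## 8. Known limitations

* The generator's ERP is deterministic within subject (no trial-to-trial
  latency or amplitude variability beyond additive noise), so epoch
  rejection rates reflect the noise model only.
* EOG regression removes any EEG genuinely correlated with EOG, including
  ERP activity leaking into the EOG leads — negligible under the generative
  model, not necessarily on real data.
* The 25 μV segment rule operates on the band-passed detection copy; with
  heavy low-frequency drift, detection-copy and analysis-path amplitudes
  can differ.
* Peak detection assumes the component peaks lie inside the published
  windows; pathological waveforms (e.g. double peaks at the window edge)
  are resolved by the extremum-plus-earliest-tie rule, which may differ
  from a human scorer.
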