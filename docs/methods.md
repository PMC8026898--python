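# Methods

This note records the models, conventions and numerical choices behind
`grfwave`, in the order the pipeline applies them, together with what
the synthetic cohorts do and do not emulate.

## Preprocessing

**Filtering.** "Zero-lag fourth-order Butterworth" is realized as a
2nd-order low-pass design applied forward and backward
(`scipy.signal.filtfilt`, odd reflective padding): the two passes give a
net 4th-order magnitude response and exactly zero phase lag. A
consequence worth stating explicitly is that the amplitude gain at the
nominal cutoff is 1/2, not 1/√2 — two passes of a −3 dB point. The
cutoff defaults to 50 Hz, conventional for running GRF; it is a
configuration parameter and is echoed into the output provenance, not a
quantity estimated from data.

**Stance detection** uses the 20 N convention on the vertical channel of
the *filtered* signal: strike is the first sample at or above threshold
of a contiguous run, toe-off the first subsequent sample below it
(exclusive end), both at sample resolution with no sub-sample
interpolation. Runs shorter than `min_contact` (default 0.100 s) are
rejected as mechanical chatter, and runs touching either end of the
recording are dropped because their true boundary was not observed.

**Resampling.** Each stance maps to 100 points at stance percentages
0, 1, …, 99 — a half-open [strike, toe-off) grid, point *i* at sample
`strike + i·n/100`. Interpolation is a natural cubic spline (linear
available by configuration) supported on the stance's own samples only;
the first post-toe-off sample is deliberately excluded so that a sharp
force drop cannot ring backwards into the curve. Forces are divided by
body weight (mass × 9.8 m/s², the constant kept at 9.8 exactly, not
9.81). Vertical values are clamped at zero before normalization (filter
undershoot); the anterior–posterior channel keeps its sign. Whether
averaging precedes or follows BW normalization is immaterial (BW is a
per-subject constant); the implementation normalizes first, then
averages steps pointwise.

## VALR

The 20–80 % bounds are fractions of the *time to* the first peak, not of
its force magnitude: t20 = 0.2·t_peak, t80 = 0.8·t_peak, and
VALR = (F(t80) − F(t20))/(t80 − t20) in BW/s. Force at the two query
times is linearly interpolated on the sample grid, so queries that fall
on samples are exact. VALR is computed per step on the filtered
time-domain stance segment and then averaged across the steps of a
condition.

The impact peak is the first local maximum within the first 40 % of
stance whose topographic prominence exceeds 0.02 BW (both
configurable). When the impact transient is a shoulder rather than a
local maximum no peak exists; such steps raise a dedicated error and are
excluded from the VALR average with a count kept in the metrics table.
The window and prominence floor are declared conventions — nothing in
the data dictates them — and the defaults were chosen once to be
comfortably clear of both the mid-stance active peak and noise-scale
wiggles.

## Waveform PCA

Rows of X are the per-subject × speed averaged curves of one sex and one
channel, ordered deterministically by (speed, subject). Column means are
removed; no unit-variance scaling is applied because all 100 columns
share BW units and the limit-curve arithmetic (mean ± SD·loading) is
formulated on the centered data. The decomposition is an SVD; the number
of components kept in the model is min(m − 1, 100) and variance
fractions are taken over that full spectrum, so they sum to one.

Sign indeterminacy is resolved by orienting each loading vector so its
element of largest absolute value is positive (ties break to the
earliest index); two fits of the same matrix are therefore bitwise
identical. Score standard deviations use the m − 1 denominator. A matrix
of identical rows has zero total variance and yields a degenerate model:
the mean curve and an empty component list.

Component retention takes the smallest k whose cumulative variance
fraction reaches the coverage target (default 0.95), capped at 4; when
the cap binds, the achieved coverage is reported alongside so the
shortfall is visible.

**Limit curves and regions.** For component k, upper/lower =
mean ± SD(z_k)·loading_k. The "region" report thresholds the separation
d = upper − lower at ε·max|d| (default ε = 0.05) and returns maximal
runs of stance points with d above (below minus) the threshold as
inclusive [start %, end %] intervals. The ε rule is a declared
convention for turning a continuous loading into printable intervals;
raw sign runs (ε = 0) are always written next to the thresholded ones.
PCA is fitted separately per sex and per channel, never pooled across
sexes.

## Group statistics

The sex comparison at each speed is an independent-samples Student
t-test (pooled variance; Welch available), mean difference reported as
female − male. The within-sex speed analysis is a one-way
repeated-measures ANOVA — the F test is inherently one-tailed — computed
via `pingouin.rm_anova`, with the Greenhouse–Geisser-corrected p-value
used when the sphericity estimate ε < 0.75. Pairwise speed contrasts use
Tukey's HSD with the studentized-range distribution on the
within-subject error mean square (q = |Δmean|/√(MS_err/n), df = error
df); this is the repeated-measures form of the test, which is why it is
computed directly from the ANOVA decomposition rather than through a
between-groups Tukey routine. Pairwise contrasts are two-sided with the
family-wise Tukey adjustment; α = 0.05 throughout. Degenerate tables
(no condition effect at all) short-circuit to F = 0, p = 1.

## Synthetic cohorts

**Shapes.** The vertical template is two Gaussian bumps — impact
(default 1.6 BW at 13 % stance, width 4 %) and active (2.4 BW at 45 %,
width 15 %) — multiplied by a cosine taper that brings the curve to
exactly zero over the first and last 2 % of stance. The
anterior–posterior template is a braking half-sine (−0.25 BW) followed
by a propulsion half-sine (+0.25 BW) crossing at 50 %. The
medial–lateral channel is zero-mean noise, reflecting how inconsistent
that component is across runners. These are minimal morphological
emulations, not a mechanistic (e.g. mass–spring) gait model.

**Variation modes**, drawn once per subject and shared across that
subject's speeds (the repeated-measures structure the statistics
assume), each a Gaussian score:

* *magnitude* (SD 0.08): all amplitudes × (1 + s) — a linear mode, which
  is what makes planted-mode PCA recovery exactly analysable;
* *timing* (SD 1.5 %): bump centers and the ant–post crossover shifted
  by s percent of stance;
* *loading rate* (SD 0.10): the impact bump compressed self-similarly
  toward strike (center and width both divided by 1 + s). Compressing
  the whole rising edge — rather than narrowing the width at a fixed
  center — is what makes VALR increase monotonically with the score: a
  time compression F(t/a) multiplies VALR by a, whereas narrowing the
  width alone would *reduce* F80 − F20 at an unchanged t_peak and drag
  VALR down.

**Effects and noise.** Speed multiplies amplitudes (1.00/1.05/1.10/1.18
at 2.7/3.0/3.3/3.7 m/s) and shortens contact time linearly (0.26 s at
the slowest speed, −0.04 s per m/s), so loading grows with speed through
both channels. The default sex effect offsets the female loading-rate
score mean by +0.15, giving females a steeper impact rise — the
direction reported for female runners — while body masses are drawn per
sex (71.4 ± 3.5 kg male, 60.6 ± 2.5 kg female). Measurement noise is
white, 3 N SD by default, added to the rendered signal; flight-phase
noise is clipped to stay below the 20 N detection threshold, and a
warning is raised if noise_sd is configured ≥ threshold/3. The default
cohort is 15 runners per sex × 4 speeds × 5 steps at 1000 Hz.

**Ground truth and frames.** Because the tapered template spends its
first and last ~1–2 % of stance below 20 N, the detected stance is
slightly shorter than the rendered one — exactly as a 20 N threshold
trims real data. Planted truth (stance boundaries to the sample, peak
values and locations) is therefore recorded in the *threshold-crossed
frame*, computed by the generator on a 0.01 %-step scan of the
continuous template, independently of the analysis code. Round-trip
tests show: noiseless rendered stances are recovered with exact
boundaries, 3 N of noise moves boundaries by at most one sample, and
resampling the rendered span reproduces the planted 100-point curves to
better than 10⁻³ BW.

**What passing tests do not show.** The generator has Gaussian modes,
white noise, perfectly periodic steps and a shared template; real
cohorts have non-Gaussian inter-subject variation, autocorrelated
soft-tissue and belt noise, step-to-step kinematic variability and
genuinely different waveform families (e.g. midfoot strikers, for whom
the impact-peak search correctly fails). Results on synthetic cohorts
validate the *machinery* — segmentation, metric definitions,
decomposition algebra, test calibration — not any physiological claim.

## Determinism and numerics

All randomness flows from one integer seed through
`numpy.random.default_rng`; replicate studies derive child seeds from a
`SeedSequence`. CSV floats are written with `%.17g` and read back with
pandas' round-trip parser, sampling rates are snapped to integer Hz when
within 10⁻⁶ relative, and JSON is dumped with sorted keys — which
together make a full pipeline run byte-identical under a fixed seed.
Acquisition grids must be uniform to 1 part in 10⁶ of the sample period;
vertical forces below −50 N are rejected as sensor faults.

Problem sizes used by the test suite and the acceptance script — the
default 60-row matrices per sex, 1000 null and 200 power replicates for
t-test calibration, 20 random matrices for the PCA/eigendecomposition
cross-check — were chosen as the smallest designs at which the checked
properties are statistically unambiguous.

## Known limitations

* Overground trials, left/right limb matching and non-rearfoot strike
  patterns are out of scope; events assume a clean treadmill baseline.
* The medial–lateral channel is carried through preprocessing but not
  modeled or analysed.
* The region-extraction ε and the impact-peak prominence floor are
  conventions; interval endpoints can move by a point or two under a
  different ε.
* VALR on the standalone `metrics` CLI is computed from the averaged
  100-point curve (the only input it has); the full pipeline computes it
  per step and averages, which is the preferred estimate.
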