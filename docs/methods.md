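# Methods

`respicycle` implements a cycle-by-cycle, multidimensional analysis of
respiratory recordings from anesthetized rodents — airflow plus raw
diaphragm (DIA) and abdominal (ABD) EMG at 1 kHz — of the kind used to
quantify pharmacologically evoked active expiration. This note documents
the model and procedure, the tunable parameters, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Signal conditioning

**EMG envelopes.** Raw EMG is rectified and leaky-integrated with a decay
time constant τ = 0.08 s. The discretization is the exponential smoother

    y[n] = a·y[n−1] + (1−a)·|x[n]|,   a = exp(−1/(fs·τ)),

with zero initial state, chosen for its unity DC gain (a sustained burst of
amplitude c converges to an envelope near c·E|ξ|) and its analytic impulse
response `(1−a)·aᵐ`, which makes the integrator exactly testable. At
fs = 1 kHz the impulse tail halves every ≈ 55 samples.

**Standardization.** Each channel (airflow, ∫DIA, ∫ABD) is converted to
baseline SD units: zeroed on the quiescent rest periods between baseline
breaths, then divided by the standard deviation of the *time-collapsed*
amplitude distribution — the RMS of the rest-zeroed signal pooled over
every sample of the 5-min baseline bin. "Pooled over all baseline samples"
is an interpretation choice: it makes the divisor insensitive to how rest
and burst samples are split, and it renders the segmentation thresholds
scale-free. The rest mask itself comes from an airflow-only bootstrap pass
(breath detection on the smoothed raw airflow; rest = the stretch between
the end of the post-I deflection and the last quarter of expiration), which
breaks the circularity between standardization and segmentation.

**Time bins.** One 300 s baseline bin ending at the start of the first
injection, then ten contiguous half-open 120 s response bins clocked from
the *end of the second injection* (response delays are defined against that
event). Trailing bins truncated by the end of the recording are computed
but flagged partial and excluded from group statistics.

## Breath detection and mean-cycles

Inspiratory onsets are upward zero crossings of airflow guarded by a
hysteresis pair (below −ε then above +ε, ε = 0.05 SD) and a minimum cycle
duration of 0.3 s. An onset requires a preceding below-band excursion, so
chatter around zero cannot fire the detector; the price is that an onset at
the very first sample of a trace cannot be armed and is not emitted.
Detection (and the airflow channel fed to the mean-cycle) runs on a 25 ms
moving-average copy of the standardized airflow: at 1 kHz the raw sensor
noise (≈ 0.03 SD per sample) crosses a 0.05 SD band freely, while the
smoothed copy keeps sub-0.01 SD noise and shifts onsets by at most half the
window (≈ 12 ms, ~1% of a cycle). A consequence worth knowing: measured
Ti carries a small positive bias (~0.03 s) from the early onset plus the
delayed downward crossing; the bias is common to baseline and response and
cancels in all relative measures.

Cycles of variable duration are aligned by linear time-normalization onto a
fixed N = 200 grid from onset to next onset (grid point k at fractional
position k/N). The paper-style per-timepoint statistics then follow
directly: mean μ_t, SD, and the unbiased 3×3 covariance Σ_t across the
cycles of a bin (~220 baseline cycles, ~80–90 per response bin at the
default breath timing).

## Phase segmentation

The mean airflow of each bin is segmented by its zero crossings:
inspiration `[0, first downward crossing)`; post-I from there until airflow
returns to ≥ 0; late-E either the terminal below-zero excursion preceding
the next onset — accepted as "significant" when it stays below 0.5 SD for
at least 2% of the grid (both thresholds exposed in `PipelineConfig`;
no criterion is stated in the source methodology) — or, as fallback, the
last quarter of the expiratory period; rest is the remainder. The four
ranges always partition `[0, N)`, which makes per-phase AUCs exactly
additive. Two open points were resolved as follows: boundaries are
*recomputed per bin* on that bin's own mean airflow (per-condition
boundaries, matching how segmentations are displayed per condition), and a
merged post-I/late-E excursion (airflow never returning to zero) is split
at the sample closest to zero between the two troughs, with an empty rest
phase and a logged warning.

With the default generator amplitudes the late-E airflow deflection
(−0.014 to −0.033 V ≈ 0.1–0.2 SD) is real but *below* the 0.5 SD
significance threshold, so segmentation stays in last-quarter mode — which
contains the injected late-E burst (last 20% of expiration) anyway. The
negative-deflection path is exercised by dedicated fixtures.

## Metrics

* RR = 60 / mean cycle duration; Ti = (inspiratory grid fraction) × mean
  duration; Te = duration − Ti.
* V_T integrates airflow over the inspiratory phase only (the quantity is
  the inspired volume per breath), converted to ml through an ordinary
  least-squares line fitted to the five-point airflow-integral/volume
  calibration, normalized by body mass. V_E = V_T · RR.
* V_O2 uses the open-circuit form with only O2 fractions measured:
  V_O2 = V_E·(FiO2 − FeO2)/(1 − FiO2).
* Per-phase AUC is the plain signed sum of the mean-cycle signal over the
  phase's grid points, response minus baseline; sub-zero signal contributes
  negatively.
* Late-E peak amplitude is the late-E minimum of the mean airflow in
  original volts (de-standardized); late-E area integrates only its
  sub-zero portion (V·s).
* Bursts are maximal supra-threshold runs of a standardized envelope with
  runs closer than 150 ms merged. The pipeline uses k = 2 SD for DIA and
  k = 10 SD for ABD (library default 3): the DIA baseline *contains* its
  inspiratory bursts, which inflate the pooled SD so genuine bursts sit
  near 3.3 SD while the floor sits near 0.005 SD; the ABD baseline is
  silent, so its pooled SD is the noise floor itself — floor excursions
  reach ~4 SD while response bursts exceed 40 SD. Both thresholds are
  config entries.
* ABD response delay = first ABD burst onset − end of second injection
  (negative when earlier); duration = minutes between first and last ABD
  burst; the ABD:DIA coupling ratio counts breaths with expiratory ABD
  activity over the first 10 response minutes, with the window capped at
  the last ABD burst (the fade-exclusion rule) and opened at the DIA burst
  of the breath carrying the first ABD burst. A breath counts as coupled
  when an ABD event starts within its inter-DIA interval or covers at
  least half of it; the half-interval rule lets a sustained tonic event
  credit the breaths it spans while the envelope's decay tail (~0.3 s
  above threshold after a burst) cannot credit the following breath.

## Trajectory distances

Each mean-cycle timepoint is a point in (airflow, ∫DIA, ∫ABD) space; a
breath is a loop. For the three reported phases (late-E "tail",
inspiratory "bulb", post-I "foot") the response phase is linearly
resampled to the baseline phase's point count and two per-point distances
are averaged over the phase:

* Euclidean: d_t = √(ΔAir² + ΔDia² + ΔAbd²);
* Mahalanobis: d_t = √((R_t − μ_t)ᵀ Σ_t⁻¹ (R_t − μ_t)), with Σ_t the
  baseline per-timepoint covariance.

The square-root (distance-unit) Mahalanobis form is the default since the
measure is interpreted in units of baseline SD; the squared form is a
config switch (`mahalanobis_squared`). The *mean* over phase points is
reported; sums are mean × n_points. Σ_t is inverted by Cholesky solve; on
failure a ridge λI with λ = 10⁻⁸·trace(Σ_t)/3 is added once, remaining
singular points are skipped and counted, and results with > 20% skipped
points are flagged. The rest phase is excluded from distance reporting.

## The synthetic generator

`respicycle.synth` emulates only the statistical structure the analysis
assumes. A baseline breath is a positive inspiratory half-sine (width Ti =
0.318 s), a negative post-I half-sine over the first 30% of Te (Te =
1.029 s), and exact zero for the rest of expiration; DIA is zero-mean
broadband noise amplitude-modulated by a raised-cosine inspiratory
envelope; ABD is noise floor only. Per-breath timing and amplitude jitter
are log-free Gaussian factors (CV 3% and 5%). Responses are defined by
location presets encoding reported group values — onset delay relative to
the second injection (+0.6 mm: −88.7 s; −0.2 mm: +20.3 s; …), duration
(17.6 / 2.4 min), ABD:DIA coupling probability (0.89 / 0.6), late-E airflow
depth (−0.033 / −0.014 V), plus rate and tidal-amplitude scalings matching
the reported percentage changes. Unreported values (+0.1/+0.4 mm durations,
+0.1 mm coupling) were fixed once at plausible intermediates (12 min,
15 min, 0.8). Within the response window each breath independently draws
its late-E ABD burst (last 20% of expiration, ending at the next onset)
with the concurrent negative airflow deflection; the +0.8 mm preset adds a
tonic expiratory component and the rostral presets a post-I ABD component.
All modifications ramp linearly over 30 s at both window edges. The period
change is absorbed entirely by Te (responses lengthen expiration), and
rr_scale multiplies the *rate*. One master seed spawns per-channel child
streams, so recordings are bit-reproducible; injections end at 430 s and
560 s by default, leaving a 5-min baseline and 20 min of post-injection
signal in an 1800 s recording.

Gas fractions are constants (FiO2 = 0.30 for supplemental oxygen; FeO2 =
0.263 chosen so baseline V_O2 lands near 17.5 ml·min⁻¹·kg⁻¹ at 0.35 kg),
so measured V_O2 tracks V_E. The five-point calibration spans 0.5–5 ml
with zero intercept.

**What this does not emulate — and what passing tests therefore do not
show.** No cardiogenic or movement artifacts, no electrode drift, no
baseline ABD tone, no chemoreflex feedback coupling gas fractions to
ventilation, no apneas or sighs, and EMG noise is white rather than
300–1000 Hz band-limited. Because the synthetic baseline ABD channel is
nearly silent, its pooled SD is tiny and response deformations measure
hundreds of SD units — far larger than the few-SD distances typical of
real recordings, where baseline EMG variability is substantial. Parameter
recovery here validates the machinery (segmentation, alignment, distance
algebra, timing logic), not robustness to physiological artifact.

## Sizes and determinism

Default problem sizes: 1800 s recordings at 1 kHz (≈ 1250 breaths), N =
200 grid, 20 seeds for null/recovery studies — one recording generates and
analyzes in well under a second, a 20-pair recovery study in under a
minute. All randomness flows from explicit integer seeds; identical seeds
give bit-identical recordings and byte-identical reports.

## Known limitations

* Ti/Te carry the small smoothing-induced bias described above (absolute
  values only; relative measures are unaffected).
* The coupling ratio credits a breath from a tonic event covering ≥ 50% of
  it, so a strong tonic preset (+0.8 mm) measures coupling ≈ 1.0 even when
  the phasic burst probability is 0.97.
* Phase boundaries are recomputed per bin; with very weak responses the
  late-E mode can alternate between bins (mode is recorded per bin in the
  metrics table).
* Group statistics here use the rank-based path (Kruskal–Wallis +
  Dunn/Sidak) that gates the per-bin comparisons; repeated-measures ANOVA
  variants are delegated to standard libraries and not re-derived.
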