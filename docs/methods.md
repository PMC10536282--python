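# Methods

This note documents the models, parameters and numerical choices behind
`gaitmark`: what the synthetic-data generator emulates (and what it does
not), how ground truth and labels are defined, how the classifier and the
similarity analysis are configured, and where the design was genuinely open.

## 1. Signals and conventions

A recording is one subject × condition trial with two channels on a uniform
100 Hz grid: `gyro_y`, the sagittal-plane foot angular velocity about the
mediolateral axis (deg/s; dimensionless after normalization; positive =
dorsiflexion-direction rotation — the sign convention is fixed here, as
sensor mountings differ), and `vforce`, the vertical foot–ground force in
newtons (≥ 0). Sample indices are 0-based on the post-resampling grid.
Conditions combine a treadmill speed ∈ {0.4, 0.8, 1.2, 1.6} m/s with a
support level: `none`, `bws30`, `bws50` (overhead harness on land, 0/30/50%
bodyweight) or `waist`, `chest` (immersion depths providing ≈30%/≈50%
buoyant unloading).

## 2. The gait simulator

The generator provides seeded synthetic cohorts in place of human
recordings. It is built from a periodic stride template evaluated stride
by stride.

**Gyro template.** A periodic cubic spline through pinned control points
(`GYRO_CONTROL_POINTS`), parameterized by the stance fraction. The shape
follows the characteristic foot-gyro waveform: a negative-to-positive
zero-crossing exactly at IC, a low positive "heel-rocker" bump through
stance, a positive-to-negative crossing just before FO descending into the
plantarflexion trough around FO, the dominant positive dorsiflexion peak at
mid-swing, and a shallow pre-IC trough — four sign changes per stride, two
per direction. Underwater the whole gyro waveform is delayed relative to
the contact events by `ic_lead` seconds (default 0.06 s; 0 on land), so the
zero-crossing *follows* IC — the timing discrepancy that makes land-trained
models fail underwater. The lead's magnitude is a declared default: the
phenomenon's direction is established, its size is not quantified in
published group data.

**Force template.** Zero throughout swing; during stance a smooth
(quintic-smoothstep, C² at the edges) build-up and release around a
double-humped load curve (loading/unloading peaks, mid-stance valley;
hump-to-valley modulation 25% on land, 10% underwater where insole-summed
force is smoother), normalized so every stride peaks at exactly
(1 − support fraction) × bodyweight (default 700 N). A constant 12 N
contact pedestal spans stance so the very first and last stance samples
already exceed the 10 N event threshold: the threshold detector applied to
the raw force therefore recovers the generator's ground truth *exactly*,
which the tests rely on. The C² shape keeps the force train spectrally
compact — steep shoulders would leave band-limitation ripple above the
10 N threshold after any low-pass filtering.

**Variability.** Per-stride durations are Normal(mean, (cv·mean)²)
truncated at ±3 SD (cv = 0.03); per-stride amplitudes are jittered the same
way (cv = 0.05); each subject carries a fixed amplitude multiplier
(Normal(1, 0.1²), truncated); white Gaussian sensor noise (sd 5 deg/s) is
added to the gyro only — the force channels in the study setting are
essentially noise-free at the 10 N scale. Stride durations default to
1.8/1.4/1.1/0.95 s and stance fractions to 0.66/0.63/0.60/0.57 for
0.4/0.8/1.2/1.6 m/s: stance occupies a larger share of slower strides
(standard gait values). The speed-dependent stance fraction matters: with a
single shape merely time- and amplitude-scaled, different speed × support
combinations alias onto one another — a degeneracy real gait does not have
— and condition transfer becomes artificially ill-posed. Base gyro
amplitude grows with speed (150 + 150·v deg/s) and is attenuated per
condition (1.0/0.95/0.90 on land; 0.75/0.65 underwater, where drag slows
the foot).

**Determinism.** One root seed; per-recording streams derive from
(seed, subject, speed, condition) via `SeedSequence` + CRC32, so any
recording can be regenerated in isolation and cohorts are reproducible
elementwise.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: measurement noise and drop-outs in the force
channel; double-support crossover forces on a shared treadmill belt;
asymmetry, fatigue and non-stationarity; speed- or depth-dependent changes
in waveform *shape* beyond the stance-fraction and amplitude effects;
inter-subject differences beyond a scalar amplitude factor. Performance
numbers on synthetic cohorts characterize the pipeline's correctness and
its sensitivity to the modeled effects (amplitude scaling, timing lag),
not expected accuracy on human recordings.

## 3. Preprocessing

Signals are downsampled to 100 Hz (polyphase, anti-aliased; upsampling is
refused), and the gyro is low-pass filtered with a 4th-order Butterworth at
4 Hz applied forward–backward. Zero-phase filtering is essential: phase lag
would shift event timing, the very quantity being learned. Per subject and
environment, the central portion of each trial is extracted (180 s on
land, 120 s underwater; shorter records keep everything except a
12-sample filter-edge margin), then all gyro channels are divided by the
subject's maximum |filtered gyro| in the reference condition — fastest
speed without support on land, fastest speed at waist depth underwater —
so the reference recording peaks at exactly 1. Order: filter → extract →
normalize (the reference scalar is computed on the extracted portion).

Ground-truth thresholding runs on the resampled but **unfiltered** force.
This is a deliberate design choice: a 4 Hz filter applied to a
several-hundred-newton periodic force train leaves Gibbs ripple of 15–40 N
in the swing-phase valleys — above the 10 N threshold — which a
first-crossing detector canonizes as spurious events (we measured IC
displaced by ~0.25 s and occasional chain breaks at 1.6 m/s, where swing
lasts only ~0.4 s). Filtering the force buys nothing here (the channel is
noise-free at threshold scale) and provably corrupts the events;
`preprocess_recording(filter_force=True)` remains available for export or
plotting.

## 4. Events and labels

`detect_threshold_events` marks IC at the first index where force rises
through the threshold (10 N) and FO where it falls back, discards crossings
within a 0.25 s refractory of the previous same-type event (the fastest
plausible stride is far longer, so anything closer is chatter), and
enforces IC/FO alternation.

`build_labels` writes class 1 (IC) / 2 (FO) over offsets −5…+4 around each
event, clipped at record boundaries. "Ten samples centered" on an even
width is ambiguous; −5…+4 keeps the event sample inside its window and is
deterministic. Where IC and FO windows overlap (conceivable at extreme
cadence), the later event keeps the contested samples — it announces the
upcoming transition.

`predictions_to_events` inverts the labeling: maximal runs of a class,
merged when closer than 0.25 s, yield one event at the run's median index
(lower middle for even runs) if at least 3 samples long — one- and
two-sample islands are treated as classifier noise. On clean labels this
recovers every event within ±1 sample (the median of a 10-sample window is
one below its center). Event-timing evaluation greedily matches predicted
to true events of the same type within ±0.1 s; unmatched truth events are
misses, unmatched predictions spurious; errors are signed
(predicted − truth) in seconds.

## 5. Features

Seven per-sample columns from the filtered, normalized gyro: the value
itself; RMS, skewness, excess kurtosis and variance over a centered
5-sample window; the central-difference derivative (×fs; one-sided at the
ends); and the zero-crossing flag (sign change relative to the previous
sample, a zero touched from a nonzero value counting once). Moments are
population moments; windows with variance < 1e-12 report skewness and
kurtosis 0 rather than NaN; edges use reflected padding so the table stays
row-aligned with the labels. Windows are centered, not trailing, because
the labels themselves are event-centered. The identity
rms² = variance + mean² holds per window to 1e-10 and is tested.

## 6. Classification and evaluation

A scikit-learn random forest, 100 trees, unlimited depth, `n_jobs=1`,
seeded. Splits never divide a gait cycle (IC-to-next-IC span; the partial
leading/trailing spans join their neighboring cycle): designs A and C
shuffle whole cycles and train on the first ⌈0.8·n⌉, designs B and D hold
out whole subjects (defaults: the last 2 of the land cohort, the last 1 of
the water cohort, by sorted ID). Metrics: 3×3 confusion matrix, per-class
one-vs-rest precision/recall/F1 with the 0/0 → 0 convention, accuracy =
trace/total. Ten-fold cross-validation partitions *cycles*, not samples —
sample-level folds would leak through the 5-sample feature windows and the
10-sample label windows. CV runs within the training pool (a transfer
test set has no folds to rotate); both numbers appear in the report when
requested. No resampling or class weighting is applied beyond the boundary
augmentation. A built-in diagnostic (`fit(permute_train_labels=...)`)
shuffles training labels and must collapse event-class F1; it guards
against any leakage path from features to labels across the split.

## 7. Similarity analysis

For a condition pair at one speed: five consecutive IC-to-IC strides are
extracted starting at the mid-record cycle, linearly resampled to a fixed
per-speed length (800 samples at 0.4 m/s, 600 at 0.8 and 1.2, 400 at 1.6 —
slower strides span more raw samples), and compared by zero-lag Pearson
correlation; iteration k slides both windows k cycles forward, and ten
iterations are averaged. Deterministic sequential windows were chosen over
random draws for reproducibility. Where the two conditions share subjects
the comparison is within-subject; across disjoint cohorts (land vs water
subjects) all subject pairings are averaged. Segments are aligned by
stride index only — both start at an IC; no lag search or time warping —
so a genuine phase shift (the underwater lag) lowers the coefficient, as
it should.

## 8. Numerical and policy details

* CSV I/O prints floats via `repr` (shortest round-tripping form), so
  write → read is bit-exact; metadata sidecars are JSON (YAML accepted).
* Filtering requires > 3·(2·order+1) samples (the forward–backward pad).
* `EventSet` validation enforces strictly increasing indices and IC/FO
  alternation; predicted event sets skip the alternation check, since a
  classifier may legitimately miss one side of a stride.
* Degenerate inputs: all-zero force → empty event set (not an error);
  constant gyro → all-zero feature table; an all-background prediction →
  empty event set.
* Problem sizes in the test suite and acceptance script (e.g. 12 × 4 × 3
  × 60 s cohorts for the in-domain design, 30 s recordings for the
  transfer and similarity checks) were chosen as the smallest cohorts that
  keep every split well-populated (hundreds of cycles per pool) while
  running comfortably on a single CPU.

## 9. Known limitations

The simulator's waveform is a single smooth template per stride — real
foot-gyro data contain impact transients, multi-peak stance detail and
richer between-subject shape variation, all of which make per-sample
classification substantially harder than it is here; synthetic in-domain
scores therefore overstate what the same pipeline achieves on human
recordings. The underwater model changes only timing,
amplitude and force-hump smoothness; real hydrodynamics also reshape the
swing profile. Event definitions assume a single foot and no crossover
contamination of the force channel. The CLI's `data_dir` path expects the
package's own CSV/JSON layout; vendor formats are out of scope.
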