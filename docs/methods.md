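# Methods

`imagentrain` implements a split-group inter-trial phase-coherence (ITC)
analysis for detecting neural entrainment to a *self-paced* covert rhythm —
the kind of signal produced when a participant imagines singing a well-known
song — together with a seeded synthetic-data generator that provides ground
truth for every stage. This note documents the models, the parameters that
matter, the numerical choices, and the limits of what the simulations can
show.

## The experimental design being modeled

Each trial pairs a *listening* presentation of the first line of a song with
an *imagery* reproduction of it, cued visually and terminated by a button
press; the cue-to-press interval is the trial's reaction time (RT). Four
blocks of 24 trials (6 per song per block) give 24 trials per song. Four
songs are presented; three enter the analysis (the fourth is reserved for an
unrelated question). The three analyzed stimuli are characterized by
duration, syllable count and syllabic rate: 6.24 s / 16 / 2.56 s⁻¹,
7.38 s / 23 / 3.12 s⁻¹, and 5.42 s / 13 / 2.40 s⁻¹ — all syllabic rates in
the delta band (1–3 Hz).

## The statistical problem and the split-group idea

For passive listening, every trial of a song carries the same rhythm at the
same rate, so phase coherence across trials at the stimulus rate indexes
entrainment directly. Imagery has no such fixed clock: the covert
reproduction is stretched or compressed from trial to trial, so pooling all
trials destroys phase alignment even if each trial is perfectly rhythmic
internally. The split-group analysis turns this liability into the contrast
of interest: within each (subject, song) stratum, RTs are z-scored and
trials ranked by |z|; the 12 trials closest to the stratum mean form the
*center* group (similar durations → aligned phase trajectories) and the
other 12 the *dispersed* group (variable durations → misaligned phases).
If neural activity tracks the imagined rhythm, the center group must show
higher ITC than the dispersed group; if not, the two groups — identical in
task, stimulus and everything except timing variance — are exchangeable.

For the listening condition the analogous contrast is *within*-groups (the
24 trials of one song) against *between*-groups (8 trials from each of the 3
songs, i.e. rhythm-scrambled while preserving trial count). The
between-group construction is repeated 100 times with fresh disjoint
samplings, and the per-channel 50th percentile (linear interpolation) of the
resampled ITC is the baseline.

## Phase extraction and ITC

Phases come from a sliding-window Fourier transform: 500-ms windows stepped
by 200 ms over the analysis window (default 0–4 s after onset), giving
frame centers at k·0.2 s for k = 0 … floor((L − 2·step)/step) — 19 frames
for a 4-s window, 29 for 6 s. Each frame spans its center ±250 ms, drawing
on neighboring epoch samples when it overhangs the analysis window (the
epoch must cover the overhang; the error message states the required
padding). Per frame the segment is mean-detrended, tapered (Hann by
default; a rectangular option preserves analytically exact cases),
zero-padded to 1 s so the 1–48 Hz grid at 1-Hz resolution lies exactly on
DFT bins, and transformed. Phases are principal values in (−π, π],
cosine-referenced at the frame center: a cosine peaking at the center has
phase 0, a sine −π/2.

The framing convention (first center at the window start, last at
L − 2·step) is one of several that produce evenly stepped frames; it was
chosen because it is the unique convention under which 4 s / 0.5 s / 0.2 s
yields exactly 19 frames with 0.2-s spacing.

ITC over a set of N trials at a time-frequency point is the resultant length
of the unit phase vectors,

    ITC(t, f) = √[(Σⱼ cos θⱼ / N)² + (Σⱼ sin θⱼ / N)²] ∈ [0, 1],

equal to 1 for identical phases and concentrating around √(π/4N) for
uniform phases. Band values average ITC over the band's inclusive 1-Hz bins
(delta 1–3, theta 4–8, mu 9–12, low/mid/high beta 13–16/17–20/21–28, low
gamma 30–48 Hz), over frames in the time window, and across the three
songs, giving one value per channel per subject per trial group.

## Cluster-based permutation inference

Per channel, a two-tailed paired t statistic compares the two conditions
across subjects (df = n − 1). Channels exceeding the critical t at the
pre-cluster α = 0.001 are grouped, separately by sign, into connected
components of the sensor adjacency graph; components with ≥ 2 channels are
clusters with mass = Σ member t. The null distribution records the maximum
|mass| over clusters obtained after randomly sign-flipping each subject's
condition difference — the exchangeability permitted by the paired null;
for a paired design this is equivalent to shuffling condition labels within
subjects. With 1,000 permutations (500 in the desk-scale configuration) the
per-cluster p is the add-one estimator (1 + #{null ≥ |mass|})/(n_perm + 1),
then Benjamini–Hochberg FDR across the observed clusters at α = 0.05. The
BH step runs through `statsmodels`; its arithmetic is cross-checked against
a direct implementation in the tests. Zero-variance difference channels get
t = 0 when all differences are zero and signed infinity otherwise (they
then always exceed any finite threshold, which is the conservative choice
for the null maximum).

Statistics run in sensor space on a synthetic adjacency graph; "vertex" in
a source-space formulation maps to "channel" here. Source localization,
forward modeling and anatomical labeling are out of scope.

The *conjunction* is the intersection of channels belonging to significant
clusters in the listening contrast and in the imagery contrast. The
*time-bin* variant runs the full chain per window over four 3-s bins with
2-s overlaps (0–3, 1–4, 2–5, 3–6 s), which requires 6 s of post-onset data.

## Effect-size utilities

`minimal_detectable_dz(α, n)` = t_crit(n−1, two-tailed α)/√n is the paired
effect whose expected t sits at the critical value: 1.02 at α = 0.001,
n = 16. `required_effect_size(power, α, n, design)` solves the
noncentral-t power equation by root finding; at 80% power, α = 0.05,
n = 16 it gives dz ≈ 0.75 for a paired design and d ≈ 1.02 for a
two-sample design with n per group. A published effect size quoted without
its design is ambiguous between these two, so both variants are always
reported.

## The synthetic generator

The generator renders the design into trial epochs (trials × channels ×
samples) with:

* **Listening rhythm** — on a small connected patch of *entrained* channels,
  cos(2πf·t) at the song's syllabic rate from stimulus onset to stimulus
  offset, phase-locked to onset.
* **Imagery rhythm** — cos(2π·n_syllables·t/RT) from cue to button press:
  exactly n_syllables cycles linearly time-warped over that trial's RT, so
  the instantaneous frequency is n_syllables/RT and duration variance
  translates directly into phase variance at fixed post-cue times. This is
  the minimal model under which the center/dispersed contrast carries the
  effect. An `oscillation_onset` parameter delays the rhythm (phase then
  locks to the rhythm's own onset), emulating entrainment that takes time to
  establish; `phase_jitter` adds a per-trial Gaussian phase offset (radians
  sd) to degrade locking for power studies. Both default to 0 (strict
  locking from the cue) since the strictness of cue locking in real imagery
  is unknown.
* **RT model** — RT ~ Normal(slowdown × song duration, sd), truncated at
  zero by resampling. Defaults: slowdown 1.15 (imagined reproduction runs
  slower than the stimulus; the multiplicative form keeps the per-song
  ordering of mean RTs), sd 0.8 s.
* **Evoked onset response** — a Gaussian-envelope deflection (σ = 20 ms) at
  100 ms on all channels with a fixed random topography, emulating an
  M100-like auditory onset field.
* **Noise** — per-channel 1/f (exponent 1.0) noise synthesized in the
  frequency domain, mixed across channels by a random row-normalized matrix
  (unit per-channel RMS, spatially correlated), amplitude 1.0. With
  oscillation amplitude 1.0 the default SNR is 1.
* **Sensor layout** — a Fibonacci spiral over a 60° spherical cap with small
  seeded jitter; channels within 1.5× the mean inter-sensor spacing are
  adjacent (mean degree ≈ 7 at 157 channels). The entrained patch (default
  6 channels) is grown breadth-first from the first channel so it forms a
  single cluster under the adjacency.

Everything is deterministic given the configuration seeds; per-subject
streams are spawned from (seed, subject), so generating one subject or all
subjects yields identical data.

### Desk scale

Default simulation sizes are desk-scale: 250 Hz sampling, 50 channels,
8 subjects, 500 permutations, with the recording-scale values (1 kHz, 157
channels, 16 subjects, 1,000 permutations) available via
`RunConfig.recording_scale()`. None of the statistical structure depends on
these sizes. The simulation experiments in the test suite use 8 subjects
for the false-positive-rate study and 16 subjects — the design's actual
sample size, at which the pre-cluster threshold corresponds to dz = 1.02 —
for the patch-recovery study. Large simulations may set `dtype="float32"`
in `GenConfig`; phase estimates differ from float64 by far less than the
phase noise at any realistic SNR.

### What the generator does not emulate

No forward model or head geometry (channels are abstract sensors), no
physiological artifacts (ocular/cardiac components and their removal are out
of scope), no trial-to-trial amplitude variability or tempo drift *within*
a trial (the warp is linear), and no oscillatory background beyond 1/f
noise. Passing tests therefore certify the statistical machinery — that the
pipeline finds duration-variance-dependent coherence where it was planted
and nothing where it was not — not that real cortical imagery signals have
this structure.

## Numerical choices

* Sample (n−1) standard deviation throughout (z-scores, t statistics).
* Split ties (equal |z|) break by trial id, making the split invariant to
  input row order.
* z-scoring and splitting are per (subject, song) stratum — the only
  reading under which 12-trial groups per song are possible; cross-song
  summaries average afterwards.
* The normality χ² uses equal-probability bins under the fitted normal with
  df = bins − 3 (two estimated moments); 7 bins gives df = 4.
* The repeated-measures ANOVA is computed from explicit subject/condition/
  residual sums of squares so the arithmetic is directly testable (it is
  cross-checked against `pingouin` in the tests).
* Percentiles use linear interpolation.
* STFT frequencies must lie exactly on the padded DFT grid; off-grid
  requests are an error rather than silently snapping.
* ITC values are clipped to [0, 1] to absorb rounding above 1 for perfectly
  aligned phases.
* Imagery trials whose RT ends before the analysis window are retained with
  the oscillation simply ending at RT (flagged `short`), matching fixed
  analysis epochs regardless of RT.

## Known limitations

* The permutation null uses subject-level sign flips; with few subjects
  (n < 6) the 2ⁿ distinct flips limit the attainable p-values.
* The between-group baseline assumes the three songs have comparable
  per-song trial counts.
* Cluster inference controls error at the cluster level; channel-level
  membership of a significant cluster is descriptive, which is why patch
  recovery is evaluated with a Jaccard overlap rather than channel-wise
  error rates.
* At 250 Hz and a 1-Hz grid the band edges are exact, but a real 2.56-Hz
  stimulus rate falls between the 2- and 3-Hz bins; the delta-band average
  absorbs this, and the tests that need exact bin alignment use rates on
  the grid.
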