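"""Seeded synthetic experiments with the statistical structure the analysis assumes.

The generator emulates a rhythmic imagined-singing experiment: on each trial a
participant first listens to the opening line of a well-known song (the
*listening* condition) and then covertly reproduces it at the same tempo (the
*imagery* condition), pressing a button at the end of the imagery.  The time
between imagery cue and button press is the trial's reaction time (RT).

Ground truth planted in the sensor time series:

* listening trials carry, on a small contiguous patch of *entrained* channels,
  a sinusoid at the song's syllabic rate, phase-locked to stimulus onset;
* imagery trials carry a sinusoid completing exactly ``n_syllables`` cycles
  over that trial's RT (instantaneous frequency ``n_syllables / RT``),
  phase-locked to the imagery cue — so trials with similar RTs have similar
  phase trajectories, which is the premise the split-group ITC analysis tests;
* every trial gets an evoked onset deflection (an M100-like transient) and
  additive 1/f noise mixed across channels.

Everything is deterministic given the seeds carried by the configuration
objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SongSpec",
    "ExperimentDesign",
    "RtModel",
    "GenConfig",
    "SensorLayout",
    "TrialEpochs",
    "ALPHABET_SONG",
    "ITSY_BITSY_SPIDER",
    "BALL_GAME",
    "TWINKLE_TWINKLE",
    "DEFAULT_SONGS",
    "ANALYZED_SONGS",
    "make_design",
    "sample_rts",
    "sensor_layout",
    "contiguous_patch",
    "synthesize_epochs",
]


@dataclass(frozen=True)
class SongSpec:
    """A sung stimulus: first line of a well-known song.

    ``rate`` is the syllabic rate in syllables/second; when omitted it is
    derived as ``n_syllables / duration`` (and must agree with any provided
    value to 2 decimals).
    """

    name: str
    duration: float  # seconds
    n_syllables: int
    rate: float = None  # syllables / second

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"song {self.name!r}: duration must be > 0")
        if self.n_syllables < 1:
            raise ValueError(f"song {self.name!r}: n_syllables must be >= 1")
        derived = self.n_syllables / self.duration
        if self.rate is None:
            object.__setattr__(self, "rate", round(derived, 2))
        elif abs(self.rate - derived) > 0.005 + 1e-12:
            raise ValueError(
                f"song {self.name!r}: rate {self.rate} inconsistent with "
                f"n_syllables/duration = {derived:.4f}"
            )


# The four stimuli (duration, syllable count, syllabic rate).
ALPHABET_SONG = SongSpec("alphabet_song", 6.24, 16, 2.56)
ITSY_BITSY_SPIDER = SongSpec("itsy_bitsy_spider", 7.38, 23, 3.12)
BALL_GAME = SongSpec("take_me_out_to_the_ball_game", 5.42, 13, 2.40)
TWINKLE_TWINKLE = SongSpec("twinkle_twinkle_little_star", 6.10, 14, 2.30)

DEFAULT_SONGS = (ALPHABET_SONG, ITSY_BITSY_SPIDER, BALL_GAME, TWINKLE_TWINKLE)
#: Songs entering the phase-coherence analysis (the fourth is reserved for an
#: unrelated question and excluded, mirroring the experimental protocol).
ANALYZED_SONGS = (ALPHABET_SONG, ITSY_BITSY_SPIDER, BALL_GAME)


@dataclass(frozen=True)
class ExperimentDesign:
    """Block/trial structure of the experiment.

    ``trials`` has one row per (subject, trial slot) with columns
    ``subject, block, trial, song``; each trial slot comprises a listening
    presentation followed by an imagery reproduction of the same song.
    """

    n_subjects: int
    n_blocks: int
    trials_per_song_per_block: int
    songs: tuple[SongSpec, ...]
    analyzed_songs: tuple[SongSpec, ...]
    seed: int
    trials: pd.DataFrame = field(repr=False, compare=False, default=None)

    @property
    def trials_per_song(self) -> int:
        return self.n_blocks * self.trials_per_song_per_block

    @property
    def trials_per_subject(self) -> int:
        return self.trials_per_song * len(self.songs)

    def song(self, name: str) -> SongSpec:
        for s in self.songs:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class RtModel:
    """Normal RT model: RT ~ N(slowdown * duration, sd), truncated at 0.

    ``slowdown`` > 1 encodes that imagined reproduction runs slower than the
    heard stimulus (button-press overhead plus slowed covert production).
    """

    slowdown: float = 1.15
    sd: float = 0.8  # seconds
    distribution: str = "normal"

    def __post_init__(self):
        if self.distribution != "normal":
            raise ValueError("only the normal RT model is implemented")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class GenConfig:
    """Signal-generation parameters.

    Defaults are desk-scale: 250 Hz sampling and 50 channels keep a full
    simulated experiment tractable while preserving every statistical feature
    the analysis relies on; the recording-scale values (1 kHz, 157 channels)
    are plain parameter changes.
    """

    sampling_rate: float = 250.0  # Hz
    epoch_pre: float = 0.5  # seconds before cue/stimulus onset
    epoch_post: float = 4.25  # seconds after onset (>= longest analysis window)
    n_channels: int = 50
    n_entrained_channels: int = 6
    oscillation_amplitude: float = 1.0
    noise_amplitude: float = 1.0  # per-channel noise RMS (SNR = osc/noise)
    noise_exponent: float = 1.0  # 1/f^exponent power slope
    evoked_latency: float = 0.1  # seconds (M100-like)
    evoked_amplitude: float = 2.0
    evoked_width: float = 0.02  # Gaussian sigma, seconds
    phase_jitter: float = 0.0  # radians sd of per-trial onset phase offset
    oscillation_onset: float = 0.0  # seconds after cue at which rhythm starts
    dtype: str = "float64"  # float32 halves memory/time for large simulations
    seed: int = 0

    def __post_init__(self):
        if self.epoch_pre < 0:
            raise ValueError("epoch_pre must be >= 0")
        if not (0 < self.n_entrained_channels <= self.n_channels):
            raise ValueError("need 0 < n_entrained_channels <= n_channels")


@dataclass(frozen=True)
class SensorLayout:
    """Channel positions on a spherical cap and their adjacency graph."""

    positions: np.ndarray  # (n_channels, 3), unit sphere
    adjacency: np.ndarray  # (n, n) bool, symmetric, no self-edges
    names: tuple[str, ...]
    neighbor_radius: float  # absolute chord length used

    @property
    def n_channels(self) -> int:
        return len(self.names)


@dataclass
class TrialEpochs:
    """Trial-epoched multichannel time series with per-trial metadata.

    ``data`` is (trials, channels, samples); ``times`` is epoch-relative with
    0 at cue/stimulus onset.  ``trials`` carries subject, block, trial, song,
    condition, rt_seconds (NaN for listening) and a ``short`` flag for imagery
    trials whose RT ends before the analysis window.  ``entrained`` lists the
    ground-truth entrained channel indices (empty when loaded from a file that
    does not record them).
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    trials: pd.DataFrame
    channels: pd.DataFrame
    entrained: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def subset(self, mask) -> "TrialEpochs":
        """Epochs restricted to the trial rows selected by ``mask``."""
        idx = np.asarray(self.trials.index[mask] if mask.dtype == bool else mask)
        return TrialEpochs(
            data=self.data[idx],
            times=self.times,
            sampling_rate=self.sampling_rate,
            trials=self.trials.loc[idx].reset_index(drop=True),
            channels=self.channels,
            entrained=self.entrained,
        )


def _substream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic named substream of a base seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def make_design(
    n_subjects: int,
    n_blocks: int = 4,
    trials_per_song_per_block: int = 6,
    songs: tuple[SongSpec, ...] = DEFAULT_SONGS,
    seed: int = 0,
    analyzed_songs: tuple[SongSpec, ...] | None = None,
) -> ExperimentDesign:
    """Build the block design with a seeded presentation order.

    Each block contains ``trials_per_song_per_block`` trials of every song in
    a seeded random order, so each song totals ``n_blocks *
    trials_per_song_per_block`` trials per subject.
    """
    if min(n_subjects, n_blocks, trials_per_song_per_block, len(songs)) < 1:
        raise ValueError("all design counts must be >= 1")
    if analyzed_songs is None:
        names = {s.name for s in songs}
        analyzed_songs = tuple(s for s in ANALYZED_SONGS if s.name in names) or tuple(songs)

    rows = []
    for subj in range(n_subjects):
        trial_no = 0
        for block in range(n_blocks):
            order = [s.name for s in songs for _ in range(trials_per_song_per_block)]
            rng = _substream(seed, subj, block)
            rng.shuffle(order)
            for song in order:
                rows.append((subj, block, trial_no, song))
                trial_no += 1
    trials = pd.DataFrame(rows, columns=["subject", "block", "trial", "song"])
    return ExperimentDesign(
        n_subjects=n_subjects,
        n_blocks=n_blocks,
        trials_per_song_per_block=trials_per_song_per_block,
        songs=tuple(songs),
        analyzed_songs=tuple(analyzed_songs),
        seed=seed,
        trials=trials,
    )


def sample_rts(design: ExperimentDesign, rt_model: RtModel, seed: int = 0) -> pd.DataFrame:
    """Sample one imagery RT per trial slot.

    RT ~ Normal(slowdown * song_duration, sd), resampled until positive
    (truncation; RT <= 0 is unphysical).  Returns the behavioral table with
    columns subject, block, trial, song, condition, rt_seconds.
    """
    durations = {s.name: s.duration for s in design.songs}
    rng = _substream(seed, 0xB0)
    out = design.trials.copy()
    mu = out["song"].map(durations).to_numpy() * rt_model.slowdown
    rts = rng.normal(mu, rt_model.sd)
    n_resampled = 0
    bad = rts <= 0
    while bad.any():
        n_resampled += int(bad.sum())
        rts[bad] = rng.normal(mu[bad], rt_model.sd)
        bad = rts <= 0
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} non-positive RT draws (truncated normal)")
    out["condition"] = "imagery"
    out["rt_seconds"] = rts
    return out


def sensor_layout(
    n_channels: int = 50,
    neighbor_radius: float = 1.5,
    seed: int = 0,
    cap_half_angle: float = np.pi / 3,
) -> SensorLayout:
    """Quasi-uniform sensor positions on a spherical cap with distance adjacency.

    Channels sit on a Fibonacci spiral covering a cap of ``cap_half_angle``
    (default 60 degrees — roughly the coverage of a whole-head array), with a
    small seeded tangential jitter.  ``neighbor_radius`` is expressed relative
    to the mean inter-sensor spacing ``sqrt(cap_area / n)``; two channels are
    adjacent when their chord distance is below it.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    n = n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    u = (np.arange(n) + 0.5) / n
    theta = np.arccos(1.0 - u * (1.0 - np.cos(cap_half_angle)))  # polar
    phi = golden * np.arange(n)
    rng = _substream(seed, 0x5E)
    spacing = np.sqrt(2 * np.pi * (1 - np.cos(cap_half_angle)) / n)
    theta = np.clip(theta + rng.normal(0, 0.05 * spacing, n), 0, cap_half_angle)
    phi = phi + rng.normal(0, 0.05 * spacing, n)
    pos = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    radius = neighbor_radius * spacing
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d < radius) & ~np.eye(n, dtype=bool)
    isolated = np.flatnonzero(~adj.any(axis=1))
    if isolated.size:
        warnings.warn(
            f"{isolated.size} channel(s) have no neighbor at radius {radius:.3f}: "
            f"{isolated.tolist()}"
        )
    names = tuple(f"CH{i:03d}" for i in range(n))
    return SensorLayout(positions=pos, adjacency=adj, names=names, neighbor_radius=radius)


def contiguous_patch(layout: SensorLayout, size: int, start: int = 0) -> np.ndarray:
    """A connected channel patch of ``size`` channels grown from ``start``.

    Breadth-first over the adjacency graph; used to place the ground-truth
    entrained patch so it is recoverable as a single cluster.
    """
    if not (1 <= size <= layout.n_channels):
        raise ValueError("patch size out of range")
    seen = [start]
    frontier = [start]
    in_seen = {start}
    while len(seen) < size and frontier:
        nxt = []
        for node in frontier:
            for nb in np.flatnonzero(layout.adjacency[node]):
                if nb not in in_seen:
                    in_seen.add(int(nb))
                    seen.append(int(nb))
                    nxt.append(int(nb))
                    if len(seen) == size:
                        return np.sort(np.array(seen[:size]))
        frontier = nxt
    if len(seen) < size:
        raise ValueError("adjacency graph too sparse to grow a connected patch")
    return np.sort(np.array(seen[:size]))


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, int], exponent: float, dtype=np.float64
) -> np.ndarray:
    """Rows of unit-RMS noise with a 1/f^exponent power spectrum.

    Synthesized directly in the frequency domain: independent complex-normal
    coefficients scaled by f^(-exponent/2), inverse-transformed.
    """
    from scipy import fft as sfft

    n = shape[1]
    n_f = n // 2 + 1
    re = rng.standard_normal((shape[0], n_f), dtype=dtype)
    im = rng.standard_normal((shape[0], n_f), dtype=dtype)
    spec = re + 1j * im
    f = np.fft.rfftfreq(n)
    gain = np.zeros(n_f, dtype=dtype)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    spec *= gain
    x = sfft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    x /= rms
    return x


def synthesize_epochs(
    design: ExperimentDesign,
    rts: pd.DataFrame,
    cfg: GenConfig,
    layout: SensorLayout,
    subjects: "list[int] | None" = None,
    conditions: tuple[str, ...] = ("listening", "imagery"),
) -> TrialEpochs:
    """Render the experiment into trial-epoched sensor data.

    Per-subject noise and jitter streams are spawned from ``cfg.seed`` and the
    subject id, so generating one subject at a time or all at once yields
    bit-identical data for that subject.
    """
    if layout.n_channels != cfg.n_channels:
        raise ValueError("layout/config channel count mismatch")
    fs = cfg.sampling_rate
    i0 = int(round(cfg.epoch_pre * fs))
    n_samp = i0 + int(round(cfg.epoch_post * fs)) + 1
    times = (np.arange(n_samp) - i0) / fs
    entrained = contiguous_patch(layout, cfg.n_entrained_channels)
    songs = {s.name: s for s in design.songs}
    rt_lookup = rts.set_index(["subject", "trial"])["rt_seconds"]

    # Fixed (seed-determined, subject-independent) spatial structure.
    struct_rng = _substream(cfg.seed, 0xA0)
    mix = struct_rng.standard_normal((cfg.n_channels, cfg.n_channels))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)  # unit-variance channels
    evoked_topo = struct_rng.normal(0, 1, cfg.n_channels)
    evoked_topo /= np.max(np.abs(evoked_topo))
    evoked_wave = np.exp(-0.5 * ((times - cfg.evoked_latency) / cfg.evoked_width) ** 2)

    if subjects is None:
        subjects = list(range(design.n_subjects))

    all_rows = []
    blocks_data = []
    t_post = times[i0:]  # t >= 0
    for subj in subjects:
        sub_trials = design.trials[design.trials["subject"] == subj]
        rows = []
        for _, tr in sub_trials.iterrows():
            for cond in conditions:
                rt = float(rt_lookup.loc[(subj, tr["trial"])]) if cond == "imagery" else np.nan
                rows.append((subj, tr["block"], tr["trial"], tr["song"], cond, rt))
        sub_df = pd.DataFrame(
            rows, columns=["subject", "block", "trial", "song", "condition", "rt_seconds"]
        )
        n_tr = len(sub_df)
        dtype = np.dtype(cfg.dtype)
        rng = _substream(cfg.seed, 0xE0, subj)
        if cfg.noise_amplitude > 0:
            src = _one_over_f_noise(
                rng, (n_tr * cfg.n_channels, n_samp), cfg.noise_exponent, dtype=dtype
            )
            src = src.reshape(n_tr, cfg.n_channels, n_samp)
            data = cfg.noise_amplitude * np.einsum("cs,tsn->tcn", mix.astype(dtype), src)
        else:
            rng.standard_normal(1)  # keep stream alignment irrespective of noise
            data = np.zeros((n_tr, cfg.n_channels, n_samp), dtype=dtype)
        jitters = (
            rng.normal(0, cfg.phase_jitter, n_tr) if cfg.phase_jitter > 0 else np.zeros(n_tr)
        )
        short = np.zeros(n_tr, dtype=bool)
        t_osc = t_post - cfg.oscillation_onset  # phase-locked to rhythm onset
        for i, row in enumerate(sub_df.itertuples()):
            song = songs[row.song]
            if row.condition == "listening":
                phase = 2 * np.pi * song.rate * t_osc
                stop = song.duration
            else:
                rt = row.rt_seconds
                phase = 2 * np.pi * song.n_syllables * t_osc / rt
                stop = rt
                if rt < cfg.epoch_post:
                    short[i] = True
            gate = (t_post >= cfg.oscillation_onset) & (t_post <= stop)
            osc = cfg.oscillation_amplitude * np.cos(phase + jitters[i]) * gate
            data[i, entrained, i0:] += osc
            data[i] += cfg.evoked_amplitude * np.outer(evoked_topo, evoked_wave)
        sub_df["short"] = short
        all_rows.append(sub_df)
        blocks_data.append(data)

    trials = pd.concat(all_rows, ignore_index=True)
    data = np.concatenate(blocks_data, axis=0)
    channels = pd.DataFrame(
        {
            "name": layout.names,
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
            "z": layout.positions[:, 2],
        }
    )
    return TrialEpochs(
        data=data,
        times=times,
        sampling_rate=fs,
        trials=trials,
        channels=channels,
        entrained=entrained,
    )
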