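"""Sliding-window phase extraction and inter-trial phase coherence (ITC).

Phases are extracted with a short-time Fourier transform: overlapping windows
(default 500 ms, stepped by 200 ms) are detrended, tapered, zero-padded to the
padded length that puts the analysis frequencies exactly on the DFT grid
(default 1 s -> 1 Hz resolution), and transformed.  The phase convention is
cosine-referenced at the frame center: a cosine peaking at the frame center
has phase 0, a sine has phase -pi/2.

ITC at a time-frequency point over a set of N trials is the length of the
mean unit phase vector,

    ITC(t, f) = sqrt[ (sum_j cos theta_j / N)^2 + (sum_j sin theta_j / N)^2 ],

which is 1 when phases are identical across trials and tends to 0 (like
~1/sqrt(N)) for uniformly random phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

__all__ = [
    "StftConfig",
    "PhaseTensor",
    "ITCMap",
    "BandSpec",
    "BANDS",
    "frame_times",
    "stft_phase",
    "itc",
    "band_average",
    "evoked_rms",
]


@dataclass(frozen=True)
class StftConfig:
    window_length: float = 0.5  # seconds
    step: float = 0.2  # seconds
    freq_min: float = 1.0  # Hz
    freq_max: float = 48.0  # Hz
    freq_resolution: float = 1.0  # Hz
    taper: str = "hann"  # or "rect"
    pad_to: float = 1.0  # seconds; sets the DFT grid spacing 1/pad_to
    analysis_window: tuple = (0.0, 4.0)  # seconds relative to onset

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.pad_to < self.window_length:
            raise ValueError("pad_to must be >= window_length")
        if self.taper not in ("hann", "rect"):
            raise ValueError("taper must be 'hann' or 'rect'")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(
            self.freq_min, self.freq_max + self.freq_resolution / 2, self.freq_resolution
        )

    @property
    def analysis_length(self) -> float:
        return self.analysis_window[1] - self.analysis_window[0]


@dataclass
class PhaseTensor:
    """Instantaneous phase per (trial, channel, frame, frequency), radians."""

    phases: np.ndarray
    frame_centers: np.ndarray  # seconds, relative to onset
    freqs: np.ndarray  # Hz
    taper: str = "hann"
    pad_to: float = 1.0

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]


@dataclass
class ITCMap:
    """ITC values in [0, 1], indexed (channel, frame, frequency)."""

    itc: np.ndarray
    frame_centers: np.ndarray
    freqs: np.ndarray
    n_trials: int


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float  # Hz, inclusive
    hi: float  # Hz, inclusive


BANDS = {
    b.name: b
    for b in (
        BandSpec("delta", 1, 3),
        BandSpec("theta", 4, 8),
        BandSpec("mu", 9, 12),
        BandSpec("low_beta", 13, 16),
        BandSpec("mid_beta", 17, 20),
        BandSpec("high_beta", 21, 28),
        BandSpec("low_gamma", 30, 48),
    )
}


def frame_times(analysis_length: float, window_length: float = 0.5, step: float = 0.2) -> np.ndarray:
    """Frame centers of the sliding-window grid.

    Centers sit at k*step for k = 0 ... floor((L - 2*step)/step); with the
    default 4 s / 0.5 s / 0.2 s this yields 19 centers (0 ... 3.6 s).  Frames
    overhang the analysis window symmetrically by window_length/2 and draw on
    adjacent epoch samples.
    """
    if analysis_length < window_length:
        raise ValueError("analysis_length must be >= window_length")
    k_max = int(np.floor((analysis_length - 2 * step) / step + 1e-9))
    k_max = max(k_max, 0)
    return np.arange(k_max + 1) * step


def _window_half_length(cfg: StftConfig, fs: float) -> int:
    return int(round(cfg.window_length * fs / 2))


def stft_phase(epochs, cfg: StftConfig = StftConfig(), freqs=None) -> PhaseTensor:
    """Extract per-trial STFT phases on the configured time-frequency grid.

    Each frame spans ``center +/- window_length/2`` (an odd number of samples,
    symmetric about the center sample); the segment is mean-detrended,
    tapered, zero-padded to ``pad_to`` and transformed; the phase is rotated
    to be referenced at the frame center.
    """
    fs = epochs.sampling_rate
    if fs < 2 * cfg.freq_max:
        raise ValueError("sampling rate below Nyquist for freq_max")
    grid = cfg.freqs if freqs is None else np.asarray(freqs, float)
    # every requested frequency must land on the padded DFT grid
    bins = grid * cfg.pad_to
    if not np.allclose(bins, np.round(bins), atol=1e-9):
        raise ValueError(
            f"frequencies {grid[~np.isclose(bins, np.round(bins))]} are not on the "
            f"{1 / cfg.pad_to:.3g}-Hz padded DFT grid"
        )
    centers = cfg.analysis_window[0] + frame_times(
        cfg.analysis_length, cfg.window_length, cfg.step
    )
    h = _window_half_length(cfg, fs)
    n_win = 2 * h + 1
    idx_c = np.round((centers - epochs.times[0]) * fs).astype(int)
    lo, hi = idx_c.min() - h, idx_c.max() + h
    n_samp = epochs.data.shape[-1]
    if lo < 0 or hi > n_samp - 1:
        need_pre = max(0.0, -(centers.min() - h / fs))
        need_post = centers.max() + h / fs
        raise ValueError(
            f"epoch does not cover the sliding windows; need samples from "
            f"-{need_pre:.3f} s to {need_post:.3f} s around onset"
        )
    taper = windows.hann(n_win, sym=True) if cfg.taper == "hann" else np.ones(n_win)
    offsets = np.arange(-h, h + 1)
    seg_idx = idx_c[:, None] + offsets[None, :]  # (frames, win)
    n_tr, n_ch = epochs.data.shape[:2]
    n_fr = len(centers)
    # contiguous gather: (trials*channels, frames*win) then frame-major rows
    flat = np.ascontiguousarray(epochs.data).reshape(-1, n_samp)
    flat = flat.take(seg_idx.ravel(), axis=1).reshape(-1, n_win)
    dtype = flat.dtype if flat.dtype in (np.float32, np.float64) else np.float64
    if len(grid) <= 8:
        # direct tapered DFT at the few requested bins, center-referenced;
        # mean removal is folded into the basis (linearity) to avoid copies
        basis = taper[:, None] * np.exp(-2j * np.pi * grid[None, :] * (offsets[:, None] / fs))
        br = np.ascontiguousarray(basis.real, dtype=dtype)
        bi = np.ascontiguousarray(basis.imag, dtype=dtype)
        m = flat.mean(axis=-1, keepdims=True)
        re = flat @ br - m * br.sum(axis=0)
        im = flat @ bi - m * bi.sum(axis=0)
        phases = np.arctan2(im, re)
    else:
        from scipy import fft as sfft

        n_pad = int(round(cfg.pad_to * fs))
        detrended = (flat - flat.mean(axis=-1, keepdims=True)) * taper.astype(dtype)
        spec = sfft.rfft(detrended, n=n_pad, axis=-1)
        k = np.round(bins).astype(int)
        coefs = spec[:, k] * np.exp(2j * np.pi * k * h / n_pad)
        phases = np.angle(coefs)
    phases = np.asarray(phases, dtype=np.float64).reshape(n_tr, n_ch, n_fr, len(grid))
    return PhaseTensor(
        phases=phases,
        frame_centers=centers,
        freqs=grid,
        taper=cfg.taper,
        pad_to=cfg.pad_to,
    )


def itc(phases, trial_indices=None) -> ITCMap:
    """Inter-trial phase coherence over a trial set.

    ``phases`` is a PhaseTensor or a (trials, ...) array of radians;
    ``trial_indices`` selects the trial subset (all trials when None).
    """
    if isinstance(phases, PhaseTensor):
        arr, centers, freqs = phases.phases, phases.frame_centers, phases.freqs
    else:
        arr = np.asarray(phases, float)
        centers = freqs = None
    if trial_indices is not None:
        idx = np.asarray(trial_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty trial set")
        arr = arr[idx]
    n = arr.shape[0]
    if n < 1:
        raise ValueError("empty trial set")
    c = np.cos(arr).sum(axis=0) / n
    s = np.sin(arr).sum(axis=0) / n
    vals = np.sqrt(c**2 + s**2)
    # guard against rounding above 1 for perfectly aligned phases
    np.clip(vals, 0.0, 1.0, out=vals)
    return ITCMap(itc=vals, frame_centers=centers, freqs=freqs, n_trials=n)


def band_average(itcmap, band, time_window=None) -> np.ndarray:
    """Mean ITC over a frequency band (inclusive) and time window, per channel.

    Accepts an ITCMap or a list of ITCMaps (e.g., one per song), in which case
    the per-channel values are additionally averaged across maps.
    """
    if isinstance(itcmap, (list, tuple)):
        return np.mean([band_average(m, band, time_window) for m in itcmap], axis=0)
    if isinstance(band, str):
        band = BANDS[band]
    fsel = (itcmap.freqs >= band.lo - 1e-9) & (itcmap.freqs <= band.hi + 1e-9)
    if not fsel.any():
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz not on the frequency grid")
    if time_window is None:
        tsel = np.ones(len(itcmap.frame_centers), dtype=bool)
    else:
        t0, t1 = time_window
        tsel = (itcmap.frame_centers >= t0 - 1e-9) & (itcmap.frame_centers <= t1 + 1e-9)
        if not tsel.any():
            raise ValueError(f"no frames inside time window {time_window}")
    return itcmap.itc[:, tsel][:, :, fsel].mean(axis=(1, 2))


def evoked_rms(epochs, trial_indices=None, search_window=(0.05, 0.2)):
    """Trial-averaged waveforms, cross-channel RMS, and RMS peak latency.

    Returns ``(mean_waveforms, rms, peak_latency)``: per-channel averages over
    the selected trials, the root-mean-square across channels per sample, and
    the latency of the RMS maximum inside ``search_window`` (None when the RMS
    is identically zero there).
    """
    data = epochs.data if trial_indices is None else epochs.data[np.asarray(trial_indices)]
    if data.shape[0] < 1:
        raise ValueError("need at least one trial")
    mean_wave = data.mean(axis=0)  # (ch, samples)
    rms = np.sqrt((mean_wave**2).mean(axis=0))
    t0, t1 = search_window
    sel = (epochs.times >= t0) & (epochs.times <= t1)
    if not sel.any():
        raise ValueError("search window outside the epoch")
    windowed = rms[sel]
    if np.all(windowed == 0):
        return mean_wave, rms, None
    peak = epochs.times[sel][np.argmax(windowed)]
    return mean_wave, rms, float(peak)
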