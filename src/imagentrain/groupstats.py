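"""Group construction, resampled baselines, and cluster-based permutation inference.

The inference chain mirrors standard nonparametric sensor statistics:

1. a per-channel paired t statistic between two conditions (subjects are the
   pairing unit);
2. channels exceeding the two-tailed critical t at a stringent pre-cluster
   alpha (default 0.001) are grouped, separately by sign, into connected
   components of the sensor adjacency graph; components with at least
   ``min_size`` channels (default 2) are candidate clusters with mass equal to
   the sum of member t values;
3. a null distribution of the maximum absolute cluster mass is built by
   randomly sign-flipping each subject's condition difference (equivalent to
   shuffling condition labels within subjects under the paired null);
4. per-cluster permutation p values (add-one estimator) are corrected across
   clusters with Benjamini-Hochberg FDR.

The listening-condition baseline follows the resampling scheme of the design:
*within*-groups are the trials of one song; *between*-groups mix k trials
from each song (rhythm-scrambled), the procedure is repeated ``n_repeats``
times, and the 50th percentile of the resampled between-group ITC serves as
the per-channel baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .behavior import GroupSplit, epoch_rows
from .spectral import BANDS, StftConfig, band_average, itc, stft_phase

__all__ = [
    "BaselineResult",
    "StatMap",
    "Cluster",
    "ClusterResult",
    "EffectSizeReport",
    "build_between_groups",
    "between_baseline",
    "paired_t_map",
    "find_clusters",
    "cluster_permutation",
    "conjunction",
    "subject_band_itc",
    "time_bin_analysis",
    "minimal_detectable_dz",
    "required_effect_size",
]


@dataclass
class BaselineResult:
    baseline: np.ndarray  # per-channel 50th-percentile ITC
    n_repeats: int
    percentile: float
    seed: int


@dataclass
class StatMap:
    t: np.ndarray  # per channel
    df: int


@dataclass
class Cluster:
    channels: np.ndarray  # sorted channel indices
    mass: float  # sum of member t values (signed)
    p: float = np.nan  # permutation p (uncorrected)
    p_fdr: float = np.nan
    significant: bool = False


@dataclass
class ClusterResult:
    clusters: list
    null_distribution: np.ndarray
    stat_map: StatMap
    pre_cluster_alpha: float
    min_size: int
    n_permutations: int
    cluster_alpha: float
    seed: "int | None" = None

    @property
    def significant_channels(self) -> np.ndarray:
        chans = [c.channels for c in self.clusters if c.significant]
        return np.unique(np.concatenate(chans)) if chans else np.array([], dtype=int)

    def to_jsonable(self, channel_names=None) -> dict:
        def nm(ix):
            return [channel_names[i] if channel_names is not None else int(i) for i in ix]

        return {
            "clusters": [
                {
                    "channels": nm(c.channels),
                    "mass": float(c.mass),
                    "p": float(c.p),
                    "p_fdr": float(c.p_fdr),
                    "significant": bool(c.significant),
                }
                for c in self.clusters
            ],
            "null_max_mass": {
                "q50": float(np.percentile(self.null_distribution, 50)),
                "q95": float(np.percentile(self.null_distribution, 95)),
                "max": float(self.null_distribution.max()) if len(self.null_distribution) else 0.0,
            },
            "params": {
                "pre_cluster_alpha": self.pre_cluster_alpha,
                "min_size": self.min_size,
                "n_permutations": self.n_permutations,
                "cluster_alpha": self.cluster_alpha,
                "seed": self.seed,
            },
        }


@dataclass
class EffectSizeReport:
    effect: float  # dz for paired, d for two-sample
    alpha: float
    power: "float | None"
    n: int
    tails: int
    design: str
    alternatives: dict = field(default_factory=dict)


def build_between_groups(trials_per_song: dict, k: int = 8, n_groups: int = 3, seed: int = 0):
    """Mixed-song trial groups for the rhythm-scrambled baseline.

    ``trials_per_song`` maps song name -> sequence of trial ids (one subject's
    listening trials).  Each of the ``n_groups`` groups receives ``k`` trials
    of every song, sampled without replacement across groups, so the groups
    are disjoint and (when k*n_groups equals the per-song trial count)
    partition all trials.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE]))
    per_group = [dict() for _ in range(n_groups)]
    for song in sorted(trials_per_song):
        ids = np.asarray(list(trials_per_song[song]))
        if k * n_groups > len(ids):
            raise ValueError(
                f"song {song!r}: k*n_groups = {k * n_groups} exceeds {len(ids)} trials"
            )
        perm = rng.permutation(ids)
        for g in range(n_groups):
            per_group[g][song] = tuple(int(t) for t in perm[g * k : (g + 1) * k])
    rule = f"between: {k} trials/song x {len(trials_per_song)} songs, no reuse"
    out = []
    for g, chunks in enumerate(per_group):
        # index under a single pseudo-stratum per song so downstream code can
        # pull the song-wise members
        idx = {(0, song): chunk for song, chunk in chunks.items()}
        out.append(GroupSplit(f"between_{g}", idx, rule=rule, seed=seed))
    return out


def _group_itc(phases, rows_by_song, band, time_window):
    """Band/time-averaged ITC of a mixed-song trial group (pooled trials)."""
    rows = np.concatenate([np.asarray(r) for r in rows_by_song.values()])
    return band_average(itc(phases, rows), band, time_window)


def between_baseline(
    phases,
    rows_per_song: dict,
    band="delta",
    time_window=(0.0, 4.0),
    k: int = 8,
    n_groups: int = 3,
    n_repeats: int = 100,
    percentile: float = 50.0,
    seed: int = 0,
) -> BaselineResult:
    """50th-percentile between-group ITC baseline over repeated regroupings.

    ``rows_per_song`` maps song name -> positional trial rows in ``phases``.
    Each repeat draws fresh disjoint between-groups, computes the band/time
    averaged ITC per group, and averages across groups; the baseline is the
    per-channel ``percentile`` (linear interpolation) over repeats.
    """
    if n_repeats < 2:
        raise ValueError("need n_repeats >= 2")
    ss = np.random.SeedSequence([int(seed), 0xBA])
    repeat_seeds = ss.generate_state(n_repeats)
    vals = []
    for r in range(n_repeats):
        groups = build_between_groups(rows_per_song, k=k, n_groups=n_groups,
                                      seed=int(repeat_seeds[r]))
        per_group = [
            _group_itc(phases, {s: g.indices[(0, s)] for s in rows_per_song}, band, time_window)
            for g in groups
        ]
        vals.append(np.mean(per_group, axis=0))
    baseline = np.percentile(np.asarray(vals), percentile, axis=0)
    return BaselineResult(baseline=baseline, n_repeats=n_repeats, percentile=percentile, seed=seed)


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray) -> StatMap:
    """Per-channel paired t statistic, subjects on axis 0.

    t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.  Channels with zero-variance
    differences get t = 0 when all differences are 0, else signed infinity.
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have matching shapes")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    d = a - b
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)
    return StatMap(t=t, df=n - 1)


def _components(nodes: np.ndarray, adjacency: np.ndarray):
    """Connected components (BFS) of the adjacency graph restricted to nodes."""
    nodes = set(int(i) for i in nodes)
    comps = []
    while nodes:
        start = nodes.pop()
        comp = [start]
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adjacency[u]):
                    v = int(v)
                    if v in nodes:
                        nodes.remove(v)
                        comp.append(v)
                        nxt.append(v)
            frontier = nxt
        comps.append(np.sort(np.array(comp)))
    return comps


def find_clusters(
    stat_map: StatMap,
    adjacency: np.ndarray,
    pre_alpha: float = 0.001,
    min_size: int = 2,
    tails: int = 2,
) -> list:
    """Candidate clusters of adjacent supra-threshold channels.

    Channels with |t| above the two-tailed critical value at ``pre_alpha`` are
    grouped into connected components separately by sign; components of size
    >= ``min_size`` are returned with mass = sum of member t values.
    """
    if tails != 2:
        raise ValueError("only two-tailed thresholding is implemented")
    t_crit = stats.t.ppf(1 - pre_alpha / 2, stat_map.df)
    clusters = []
    for sign in (1, -1):
        mask = (sign * stat_map.t) > t_crit
        if not mask.any():
            continue
        for comp in _components(np.flatnonzero(mask), adjacency):
            if len(comp) >= min_size:
                clusters.append(Cluster(channels=comp, mass=float(stat_map.t[comp].sum())))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_null_masses(diffs, signs, t_crit, adjacency, min_size):
    """Maximum |cluster mass| for each row of sign flips (vectorized t maps)."""
    n_perm, n_subj = signs.shape
    n = n_subj
    flipped_mean = signs @ diffs / n  # (n_perm, ch)
    sq = (diffs**2).mean(axis=0)  # sign flips leave d^2 unchanged
    var = (sq - flipped_mean**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmaps = flipped_mean / np.sqrt(var / n)
        tmaps = np.where(var == 0, np.where(flipped_mean == 0, 0.0,
                                            np.sign(flipped_mean) * np.inf), tmaps)
    out = np.zeros(n_perm)
    for p in range(n_perm):
        tp = tmaps[p]
        best = 0.0
        for sign in (1, -1):
            mask = (sign * tp) > t_crit
            if np.count_nonzero(mask) < min_size:
                continue
            for comp in _components(np.flatnonzero(mask), adjacency):
                if len(comp) >= min_size:
                    best = max(best, abs(float(tp[comp].sum())))
        out[p] = best
    return out


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    pre_alpha: float = 0.001,
    min_size: int = 2,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test between paired conditions.

    The null distribution records, per permutation of subject-level sign
    flips, the maximum absolute cluster mass; each observed cluster gets
    p = (1 + #{null >= |mass|}) / (n_perm + 1), then Benjamini-Hochberg FDR
    across observed clusters at ``cluster_alpha``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} < 100 gives unstable p-values")
    stat_map = paired_t_map(cond_a, cond_b)
    observed = find_clusters(stat_map, adjacency, pre_alpha, min_size)
    d = np.asarray(cond_a, float) - np.asarray(cond_b, float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1]))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.shape[0]))
    t_crit = stats.t.ppf(1 - pre_alpha / 2, stat_map.df)
    null = _max_null_masses(d, signs, t_crit, adjacency, min_size)
    for c in observed:
        c.p = (1 + int((null >= abs(c.mass)).sum())) / (n_perm + 1)
    if observed:
        reject, p_fdr, *_ = multipletests(
            [c.p for c in observed], alpha=cluster_alpha, method="fdr_bh"
        )
        for c, r, q in zip(observed, reject, p_fdr):
            c.p_fdr = float(q)
            c.significant = bool(r)
    return ClusterResult(
        clusters=observed,
        null_distribution=null,
        stat_map=stat_map,
        pre_cluster_alpha=pre_alpha,
        min_size=min_size,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        seed=seed,
    )


def conjunction(result_a: ClusterResult, result_b: ClusterResult) -> np.ndarray:
    """Channels significant in both cluster results."""
    if len(result_a.stat_map.t) != len(result_b.stat_map.t):
        raise ValueError("cluster results live on different channel spaces")
    return np.intersect1d(result_a.significant_channels, result_b.significant_channels)


def subject_band_itc(
    epochs,
    split: GroupSplit,
    band="delta",
    stft_cfg: StftConfig = None,
    condition: str = "imagery",
    songs=None,
    freqs=None,
) -> np.ndarray:
    """Per-subject per-channel band/time-averaged ITC for one trial group.

    For each subject: ITC over the group's trials of each song, band- and
    time-averaged, then averaged across songs.  Returns (n_subjects,
    n_channels).
    """
    if stft_cfg is None:
        stft_cfg = StftConfig()
    if isinstance(band, str):
        band = BANDS[band]
    if freqs is None:
        freqs = np.arange(band.lo, band.hi + stft_cfg.freq_resolution / 2,
                          stft_cfg.freq_resolution)
    subjects = sorted(epochs.trials["subject"].unique())
    if songs is None:
        songs = sorted({song for (_, song) in split.indices})
    out = np.zeros((len(subjects), epochs.n_channels))
    for si, subj in enumerate(subjects):
        mask = (epochs.trials["subject"] == subj).to_numpy()
        sub = epochs.subset(np.flatnonzero(mask))
        phases = stft_phase(sub, stft_cfg, freqs=freqs)
        maps = []
        for song in songs:
            rows = epoch_rows(split, sub.trials, subj, song, condition)
            maps.append(itc(phases, rows))
        out[si] = band_average(maps, band, stft_cfg.analysis_window)
    return out


def time_bin_analysis(
    epochs,
    split_a: GroupSplit,
    split_b: GroupSplit,
    adjacency: np.ndarray,
    bins=((0.0, 3.0), (1.0, 4.0), (2.0, 5.0), (3.0, 6.0)),
    band="delta",
    condition: str = "imagery",
    stft_cfg: StftConfig = None,
    n_perm: int = 1000,
    pre_alpha: float = 0.001,
    min_size: int = 2,
    cluster_alpha: float = 0.05,
    seed: int = 0,
):
    """Full ITC -> paired t -> cluster permutation pipeline per time bin.

    Default bins are four 3-s windows with 2-s overlaps over the first 6 s
    after onset; the epoch must cover them (plus the window overhang).
    """
    base = stft_cfg or StftConfig()
    results = []
    for i, (t0, t1) in enumerate(bins):
        cfg = StftConfig(
            window_length=base.window_length,
            step=base.step,
            freq_min=base.freq_min,
            freq_max=base.freq_max,
            freq_resolution=base.freq_resolution,
            taper=base.taper,
            pad_to=base.pad_to,
            analysis_window=(t0, t1),
        )
        a = subject_band_itc(epochs, split_a, band, cfg, condition)
        b = subject_band_itc(epochs, split_b, band, cfg, condition)
        results.append(
            cluster_permutation(
                a, b, adjacency, n_perm=n_perm, pre_alpha=pre_alpha,
                min_size=min_size, cluster_alpha=cluster_alpha, seed=seed + i,
            )
        )
    return results


def minimal_detectable_dz(alpha: float = 0.001, n: int = 16, tails: int = 2) -> EffectSizeReport:
    """Smallest paired effect whose expected t reaches the critical value.

    dz = t_crit(df = n-1, two-tailed alpha) / sqrt(n).  At alpha = 0.001 and
    n = 16 this is 1.02 (2 dp).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    a = alpha / 2 if tails == 2 else alpha
    dz = float(stats.t.ppf(1 - a, n - 1) / np.sqrt(n))
    return EffectSizeReport(effect=dz, alpha=alpha, power=None, n=n, tails=tails, design="paired")


def _noncentral_t_power(effect, n, alpha, design):
    if design == "paired":
        df, nc = n - 1, effect * np.sqrt(n)
    elif design == "two_sample":
        df, nc = 2 * n - 2, effect * np.sqrt(n / 2)
    else:
        raise ValueError("design must be 'paired' or 'two_sample'")
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(t_crit, df, nc)
    lower = stats.nct.cdf(-t_crit, df, nc)
    # the lower tail underflows to nan at large noncentrality; it is then ~0
    return float(upper + (0.0 if np.isnan(lower) else lower))


def required_effect_size(
    power: float = 0.80, alpha: float = 0.05, n: int = 16, design: str = "paired"
) -> EffectSizeReport:
    """Effect size achieving the requested power of a two-tailed t test.

    Solves the noncentral-t power equation for the standardized effect (dz
    with n pairs for ``paired``; Cohen's d with n per group for
    ``two_sample``).  Both design variants are reported in ``alternatives``
    because a printed effect size without its design is ambiguous.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if _noncentral_t_power(20.0, n, alpha, design) < power:
        raise ValueError("requested power unattainable")

    def solve(dsgn):
        return float(
            optimize.brentq(lambda d: _noncentral_t_power(d, n, alpha, dsgn) - power, 1e-9, 20.0)
        )

    alternatives = {d: solve(d) for d in ("paired", "two_sample")}
    return EffectSizeReport(
        effect=alternatives[design],
        alpha=alpha,
        power=power,
        n=n,
        tails=2,
        design=design,
        alternatives=alternatives,
    )
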