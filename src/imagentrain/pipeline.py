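"""End-to-end orchestration: simulate -> behavior -> phases -> ITC -> cluster stats.

`run_full_pipeline` reproduces the complete analysis on a synthetic
experiment: behavioral RT tests, the center/dispersed split, per-band ITC for
the four trial groupings (imagery center/dispersed, listening within/between
baseline), cluster-based permutation contrasts, the listening-vs-imagery
contrast, and the conjunction of the two main effects.  Every stochastic
stage draws its seed from the single config seed through named substreams, so
a report is fully regenerable from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

from . import behavior as bh
from . import groupstats as gs
from .io import dump_json, read_epochs, write_epochs  # noqa: F401  (re-exported surface)
from .spectral import BANDS, ITCMap, StftConfig, band_average, stft_phase
from .synthgen import (
    ANALYZED_SONGS,
    DEFAULT_SONGS,
    GenConfig,
    RtModel,
    SensorLayout,
    make_design,
    sample_rts,
    sensor_layout,
    synthesize_epochs,
)

__all__ = [
    "RunConfig",
    "seed_for",
    "run_full_pipeline",
    "simulate_imagery_contrast",
    "experiment_type1",
    "experiment_power",
    "read_epochs",
    "write_epochs",
]

_SONGS_BY_NAME = {s.name: s for s in DEFAULT_SONGS}


def seed_for(base_seed: int, label: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from a global seed."""
    return (int(base_seed) * 0x9E3779B1 + zlib.crc32(label.encode())) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a simulated experiment and its analysis."""

    n_subjects: int = 8
    n_blocks: int = 4
    trials_per_song_per_block: int = 6
    songs: tuple = tuple(s.name for s in DEFAULT_SONGS)
    analyzed_songs: tuple = tuple(s.name for s in ANALYZED_SONGS)
    rt_model: RtModel = RtModel()
    gen: GenConfig = GenConfig()
    neighbor_radius: float = 1.5
    stft: StftConfig = StftConfig()
    bands: tuple = tuple(BANDS)
    n_perm: int = 500
    pre_cluster_alpha: float = 0.001
    min_size: int = 2
    cluster_alpha: float = 0.05
    baseline_repeats: int = 100
    between_k: int = 8
    between_groups: int = 3
    time_bins: bool = False
    seed: int = 0

    @classmethod
    def recording_scale(cls, **overrides) -> "RunConfig":
        """Recording-scale settings: 16 subjects, 157 channels, 1000 permutations."""
        base = cls(
            n_subjects=16,
            gen=GenConfig(n_channels=157, sampling_rate=1000.0),
            n_perm=1000,
        )
        return replace(base, **overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("songs", "analyzed_songs", "bands"):
            d[key] = list(d[key])
        d["stft"]["analysis_window"] = list(d["stft"]["analysis_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rt_model" in d and isinstance(d["rt_model"], dict):
            d["rt_model"] = RtModel(**d["rt_model"])
        if "gen" in d and isinstance(d["gen"], dict):
            d["gen"] = GenConfig(**d["gen"])
        if "stft" in d and isinstance(d["stft"], dict):
            s = dict(d["stft"])
            s["analysis_window"] = tuple(s.get("analysis_window", (0.0, 4.0)))
            d["stft"] = StftConfig(**s)
        for key in ("songs", "analyzed_songs", "bands"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def song_specs(self) -> tuple:
        return tuple(_SONGS_BY_NAME[n] for n in self.songs)

    def analyzed_song_specs(self) -> tuple:
        return tuple(_SONGS_BY_NAME[n] for n in self.analyzed_songs)


def _behavior_report(rts: pd.DataFrame, config: RunConfig) -> dict:
    analyzed = config.analyzed_song_specs()
    table = bh.zscore_rts(rts[rts["song"].isin(config.analyzed_songs)])
    out = {
        "rt_vs_duration": {
            s.name: bh.rt_vs_duration_test(table, s).to_jsonable() for s in analyzed
        },
        "duration_increase_anova": bh.duration_increase_anova(table, analyzed).to_jsonable(),
        "zscore_normality_chi2": bh.zscore_normality_chi2(table, n_bins=7).to_jsonable(),
        "mean_rt_per_song": {
            s.name: float(table[table["song"] == s.name]["rt_seconds"].mean()) for s in analyzed
        },
    }
    return out, table


def _unit_vectors(phases) -> np.ndarray:
    return np.exp(1j * phases.phases)


def _group_map(unit, rows, phases) -> ITCMap:
    vals = np.abs(unit[np.asarray(rows)].mean(axis=0))
    np.clip(vals, 0.0, 1.0, out=vals)
    return ITCMap(itc=vals, frame_centers=phases.frame_centers, freqs=phases.freqs,
                  n_trials=len(rows))


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the complete simulated experiment and analysis; returns the report."""
    design = make_design(
        config.n_subjects,
        config.n_blocks,
        config.trials_per_song_per_block,
        config.song_specs(),
        seed=seed_for(config.seed, "design"),
        analyzed_songs=config.analyzed_song_specs(),
    )
    layout = sensor_layout(
        config.gen.n_channels, config.neighbor_radius, seed=seed_for(config.seed, "layout")
    )
    rts = sample_rts(design, config.rt_model, seed=seed_for(config.seed, "rts"))
    behavior_report, ztable = _behavior_report(rts, config)
    n_half = design.trials_per_song // 2
    center, dispersed = bh.split_center_dispersed(ztable, n_per_group=n_half)

    gen = replace(config.gen, seed=seed_for(config.seed, "epochs"))
    bands = [BANDS[b] for b in config.bands]
    window = config.stft.analysis_window
    songs = list(config.analyzed_songs)
    per_band = {
        b.name: {g: [] for g in ("center", "dispersed", "within", "between_baseline")}
        for b in bands
    }
    entrained = None
    for subj in range(config.n_subjects):
        epochs = synthesize_epochs(design, rts, gen, layout, subjects=[subj])
        entrained = epochs.entrained
        phases = stft_phase(epochs, config.stft)
        unit = _unit_vectors(phases)
        maps = {g: [] for g in ("center", "dispersed", "within")}
        listen_rows = {}
        for song in songs:
            for name, split in (("center", center), ("dispersed", dispersed)):
                rows = bh.epoch_rows(split, epochs.trials, subj, song, "imagery")
                maps[name].append(_group_map(unit, rows, phases))
            lrows = np.flatnonzero(
                (
                    (epochs.trials["condition"] == "listening")
                    & (epochs.trials["song"] == song)
                ).to_numpy()
            )
            listen_rows[song] = lrows
            maps["within"].append(_group_map(unit, lrows, phases))
        # between-group baseline: repeated mixed-song regroupings, all bands at once
        ss = np.random.SeedSequence([seed_for(config.seed, "baseline"), subj])
        repeat_seeds = ss.generate_state(config.baseline_repeats)
        repeat_vals = {b.name: [] for b in bands}
        for r in range(config.baseline_repeats):
            groups = gs.build_between_groups(
                listen_rows, k=config.between_k, n_groups=config.between_groups,
                seed=int(repeat_seeds[r]),
            )
            gmaps = []
            for g in groups:
                rows = np.concatenate([g.indices[(0, s)] for s in songs])
                gmaps.append(_group_map(unit, rows, phases))
            for b in bands:
                repeat_vals[b.name].append(
                    np.mean([band_average(m, b, window) for m in gmaps], axis=0)
                )
        for b in bands:
            for g in ("center", "dispersed", "within"):
                per_band[b.name][g].append(band_average(maps[g], b, window))
            per_band[b.name]["between_baseline"].append(
                np.percentile(np.asarray(repeat_vals[b.name]), 50, axis=0)
            )

    report_bands = {}
    for b in bands:
        arrs = {g: np.asarray(v) for g, v in per_band[b.name].items()}
        kw = dict(
            adjacency=layout.adjacency,
            n_perm=config.n_perm,
            pre_alpha=config.pre_cluster_alpha,
            min_size=config.min_size,
            cluster_alpha=config.cluster_alpha,
        )
        imagery = gs.cluster_permutation(
            arrs["center"], arrs["dispersed"], seed=seed_for(config.seed, f"perm-img-{b.name}"),
            **kw,
        )
        listening = gs.cluster_permutation(
            arrs["within"], arrs["between_baseline"],
            seed=seed_for(config.seed, f"perm-lis-{b.name}"), **kw,
        )
        contrast = gs.cluster_permutation(
            arrs["within"], arrs["center"], seed=seed_for(config.seed, f"perm-cmp-{b.name}"),
            **kw,
        )
        names = list(layout.names)
        report_bands[b.name] = {
            "imagery_center_vs_dispersed": imagery.to_jsonable(names),
            "listening_within_vs_between": listening.to_jsonable(names),
            "listening_vs_imagery": contrast.to_jsonable(names),
            "conjunction": [names[i] for i in gs.conjunction(listening, imagery)],
            "group_means": {g: float(a.mean()) for g, a in arrs.items()},
        }

    report = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "entrained_channels": [int(i) for i in (entrained if entrained is not None else [])],
        },
        "behavior": behavior_report,
        "bands": report_bands,
    }

    if config.time_bins:
        if config.gen.epoch_post < 6.0:
            raise ValueError("time-bin analysis needs epochs covering 6 s post-onset")
        epochs = synthesize_epochs(design, rts, gen, layout)
        bins = ((0.0, 3.0), (1.0, 4.0), (2.0, 5.0), (3.0, 6.0))
        results = gs.time_bin_analysis(
            epochs, center, dispersed, layout.adjacency, bins=bins, band="delta",
            stft_cfg=config.stft, n_perm=config.n_perm, pre_alpha=config.pre_cluster_alpha,
            min_size=config.min_size, cluster_alpha=config.cluster_alpha,
            seed=seed_for(config.seed, "timebins"),
        )
        report["time_bins"] = [
            {"window": list(b), **r.to_jsonable(list(layout.names))}
            for b, r in zip(bins, results)
        ]
    return report


def simulate_imagery_contrast(
    n_subjects: int = 8,
    gen: GenConfig = None,
    rt_model: RtModel = RtModel(),
    stft: StftConfig = None,
    band: str = "delta",
    n_perm: int = 500,
    pre_alpha: float = 0.001,
    min_size: int = 2,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    layout: SensorLayout = None,
) -> dict:
    """One imagery-only replicate of the center-vs-dispersed contrast.

    Simulates imagery trials of the three analyzed songs, splits them on RT,
    extracts band phases, and runs the cluster permutation test.  Returns the
    per-subject group ITC arrays, the ground-truth entrained patch, and the
    ClusterResult.  This is the unit of the type-I-error and recovery
    simulation experiments.
    """
    gen = gen or GenConfig(epoch_pre=0.3, epoch_post=3.9)
    stft = stft or StftConfig()
    bspec = BANDS[band]
    freqs = np.arange(bspec.lo, bspec.hi + stft.freq_resolution / 2, stft.freq_resolution)
    design = make_design(
        n_subjects, 4, 6, ANALYZED_SONGS, seed=seed_for(seed, "design"),
        analyzed_songs=ANALYZED_SONGS,
    )
    if layout is None:
        layout = sensor_layout(gen.n_channels, seed=seed_for(seed, "layout"))
    rts = sample_rts(design, rt_model, seed=seed_for(seed, "rts"))
    ztable = bh.zscore_rts(rts)
    center, dispersed = bh.split_center_dispersed(ztable, n_per_group=design.trials_per_song // 2)
    gen = replace(gen, seed=seed_for(seed, "epochs"))
    songs = [s.name for s in ANALYZED_SONGS]
    cvals, dvals = [], []
    entrained = None
    for subj in range(n_subjects):
        epochs = synthesize_epochs(
            design, rts, gen, layout, subjects=[subj], conditions=("imagery",)
        )
        entrained = epochs.entrained
        phases = stft_phase(epochs, stft, freqs=freqs)
        unit = _unit_vectors(phases)
        cmaps, dmaps = [], []
        for song in songs:
            cmaps.append(_group_map(unit, bh.epoch_rows(center, epochs.trials, subj, song, "imagery"), phases))
            dmaps.append(_group_map(unit, bh.epoch_rows(dispersed, epochs.trials, subj, song, "imagery"), phases))
        cvals.append(band_average(cmaps, bspec, stft.analysis_window))
        dvals.append(band_average(dmaps, bspec, stft.analysis_window))
    cvals, dvals = np.asarray(cvals), np.asarray(dvals)
    result = gs.cluster_permutation(
        cvals, dvals, layout.adjacency, n_perm=n_perm, pre_alpha=pre_alpha,
        min_size=min_size, cluster_alpha=cluster_alpha, seed=seed_for(seed, "perm"),
    )
    return {
        "center": cvals,
        "dispersed": dvals,
        "entrained": entrained,
        "result": result,
        "layout": layout,
    }


def _jaccard(a, b) -> float:
    a, b = set(map(int, a)), set(map(int, b))
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def experiment_type1(
    n_replicates: int = 50,
    n_subjects: int = 8,
    gen: GenConfig = None,
    n_perm: int = 500,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Family-wise false-positive rate of the cluster pipeline under no effect.

    Runs `simulate_imagery_contrast` with the entrained oscillation disabled
    (noise only), counts replicates with at least one significant cluster, and
    reports the rate with a 95% binomial (Wilson) interval.
    """
    gen = gen or GenConfig(epoch_pre=0.3, epoch_post=3.9)
    gen = replace(gen, oscillation_amplitude=0.0)
    hits = 0
    for r in range(n_replicates):
        res = simulate_imagery_contrast(
            n_subjects=n_subjects, gen=gen, n_perm=n_perm, seed=seed_for(seed, f"rep{r}"),
            **kwargs,
        )
        hits += int(len(res["result"].significant_channels) > 0)
    lo, hi = proportion_confint(hits, n_replicates, alpha=0.05, method="wilson")
    return pd.DataFrame(
        [
            {
                "n_replicates": n_replicates,
                "rejections": hits,
                "rate": hits / n_replicates,
                "ci_low": lo,
                "ci_high": hi,
            }
        ]
    )


def experiment_power(
    param: str = "phase_jitter",
    values=(0.0, 0.5, 1.0, 2.0),
    n_replicates: int = 20,
    n_subjects: int = 8,
    gen: GenConfig = None,
    rt_model: RtModel = RtModel(),
    n_perm: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery of the entrained patch across a generator-parameter grid.

    For each value of ``param`` (a GenConfig field, or ``rt_sd``), runs
    replicates of the imagery contrast and reports: the rate at which the
    center group's mean entrained-channel ITC exceeds the dispersed group's,
    the rate of Jaccard >= 0.5 recovery of the planted patch by the
    significant clusters, and binomial CIs.
    """
    gen = gen or GenConfig(epoch_pre=0.3, epoch_post=3.9)
    rows = []
    for v in values:
        if param == "rt_sd":
            g, rm = gen, replace(rt_model, sd=float(v))
        else:
            g, rm = replace(gen, **{param: float(v)}), rt_model
        sign_hits = jac_hits = 0
        for r in range(n_replicates):
            res = simulate_imagery_contrast(
                n_subjects=n_subjects, gen=g, rt_model=rm, n_perm=n_perm,
                seed=seed_for(seed, f"{param}={v}/rep{r}"),
            )
            ent = res["entrained"]
            diff = (res["center"][:, ent] - res["dispersed"][:, ent]).mean()
            sign_hits += int(diff > 0)
            jac_hits += int(_jaccard(res["result"].significant_channels, ent) >= 0.5)
        lo, hi = proportion_confint(jac_hits, n_replicates, alpha=0.05, method="wilson")
        rows.append(
            {
                param: v,
                "n_replicates": n_replicates,
                "sign_rate": sign_hits / n_replicates,
                "recovery_rate": jac_hits / n_replicates,
                "recovery_ci_low": lo,
                "recovery_ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
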