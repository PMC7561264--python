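"""Behavioral RT analysis and RT-based trial stratification.

The key operation is the center/dispersed split: within each (subject, song)
stratum, imagery trials are z-scored on RT and ranked by |z|; the half closest
to the stratum mean forms the *center* group (low temporal variance across
trials) and the remainder the *dispersed* group (high variance).  The two
groups are the conditions compared by the downstream phase-coherence
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSplit",
    "TestResult",
    "zscore_rts",
    "split_center_dispersed",
    "rt_vs_duration_test",
    "duration_increase_anova",
    "zscore_normality_chi2",
    "syllable_rate",
    "epoch_rows",
]


@dataclass(frozen=True)
class GroupSplit:
    """Named trial-index sets per (subject, song) stratum.

    ``indices`` maps (subject, song) -> tuple of trial ids (the ``trial``
    column of the behavioral/epoch tables, not positional rows).
    """

    name: str
    indices: dict = field(compare=False)
    rule: str = ""
    seed: "int | None" = None

    def trials_for(self, subject, song) -> tuple:
        return self.indices[(subject, song)]

    @property
    def strata(self):
        return sorted(self.indices)

    def to_jsonable(self) -> dict:
        return {
            "name": self.name,
            "rule": self.rule,
            "seed": self.seed,
            "indices": {f"{s}|{g}": [int(t) for t in v] for (s, g), v in self.indices.items()},
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "GroupSplit":
        idx = {}
        for key, v in d["indices"].items():
            subj, song = key.split("|", 1)
            idx[(int(subj), song)] = tuple(v)
        return cls(name=d["name"], indices=idx, rule=d.get("rule", ""), seed=d.get("seed"))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a classical test: statistic, df (scalar or pair), p, effect."""

    statistic: float
    df: "float | tuple"
    p: float
    effect: "float | None" = None
    name: str = ""

    def to_jsonable(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "df": list(self.df) if isinstance(self.df, tuple) else float(self.df),
            "p": float(self.p),
            "effect": None if self.effect is None else float(self.effect),
        }


def zscore_rts(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize RTs within each (subject, song) stratum.

    Adds a ``z`` column: (rt - stratum mean) / stratum sd, with the sample
    (n-1) standard deviation.  Errors on strata with fewer than 2 trials or
    zero RT variance.
    """
    out = table.copy()
    z = np.full(len(out), np.nan)
    for (subj, song), grp in out.groupby(["subject", "song"], sort=False):
        rts = grp["rt_seconds"].to_numpy(float)
        if len(rts) < 2:
            raise ValueError(f"stratum (subject={subj}, song={song}) has <2 trials")
        sd = rts.std(ddof=1)
        if sd == 0:
            raise ValueError(f"stratum (subject={subj}, song={song}) has zero RT variance")
        z[out.index.get_indexer(grp.index)] = (rts - rts.mean()) / sd
    out["z"] = z
    return out


def split_center_dispersed(table: pd.DataFrame, n_per_group: int = 12):
    """Split each (subject, song) stratum into center and dispersed halves.

    Trials are ranked by |z| ascending, ties broken by trial id (stable): the
    first ``n_per_group`` form the center group, the remaining ``n_per_group``
    the dispersed group.  Returns ``(center, dispersed)`` GroupSplits.
    """
    if "z" not in table.columns:
        table = zscore_rts(table)
    center, dispersed = {}, {}
    for (subj, song), grp in table.groupby(["subject", "song"], sort=False):
        if len(grp) != 2 * n_per_group:
            raise ValueError(
                f"stratum (subject={subj}, song={song}) has {len(grp)} trials; "
                f"need exactly {2 * n_per_group}"
            )
        order = np.lexsort((grp["trial"].to_numpy(), np.abs(grp["z"].to_numpy())))
        ranked = grp["trial"].to_numpy()[order]
        center[(subj, song)] = tuple(int(t) for t in ranked[:n_per_group])
        dispersed[(subj, song)] = tuple(int(t) for t in ranked[n_per_group:])
    rule = f"|z| rank, ties by trial id; first {n_per_group} -> center"
    return (
        GroupSplit("center", center, rule=rule),
        GroupSplit("dispersed", dispersed, rule=rule),
    )


def rt_vs_duration_test(table: pd.DataFrame, song) -> TestResult:
    """One-sample t test of per-subject mean RT against the song's duration."""
    sub = table[table["song"] == song.name]
    means = sub.groupby("subject")["rt_seconds"].mean().to_numpy()
    n = len(means)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    if means.std(ddof=1) == 0:
        # degenerate but well-defined: no variability around the duration
        stat = 0.0 if means.mean() == song.duration else np.inf * np.sign(means.mean() - song.duration)
        return TestResult(statistic=float(stat), df=float(n - 1),
                          p=1.0 if stat == 0 else 0.0, effect=None,
                          name=f"rt_vs_duration[{song.name}]")
    res = stats.ttest_1samp(means, song.duration)
    dz = (means.mean() - song.duration) / means.std(ddof=1)
    return TestResult(
        statistic=float(res.statistic),
        df=float(n - 1),
        p=float(res.pvalue),
        effect=float(dz),
        name=f"rt_vs_duration[{song.name}]",
    )


def duration_increase_anova(table: pd.DataFrame, songs) -> TestResult:
    """One-way repeated-measures ANOVA on per-subject duration increase.

    The dependent value is mean RT minus song duration for each (subject,
    song) cell.  Computed from explicit sums of squares — subject, condition
    (song) and residual — so the arithmetic is directly checkable:

        F = (SS_song / (k-1)) / (SS_resid / ((k-1)(n-1)))
    """
    durations = {s.name: s.duration for s in songs}
    cells = (
        table[table["song"].isin(durations)]
        .groupby(["subject", "song"])["rt_seconds"]
        .mean()
        .unstack("song")
    )
    if cells.isna().any().any():
        missing = [tuple(ix) for ix in zip(*np.where(cells.isna()))]
        raise ValueError(f"missing (subject, song) cells: {missing}")
    y = cells.to_numpy() - np.array([durations[c] for c in cells.columns])
    n, k = y.shape
    grand = y.mean()
    ss_song = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_resid = ss_tot - ss_song - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_song, ms_resid = ss_song / df1, ss_resid / df2
    f = 0.0 if ms_song == 0 else ms_song / ms_resid
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(statistic=float(f), df=(float(df1), float(df2)), p=p,
                      name="duration_increase_rm_anova")


def zscore_normality_chi2(table: pd.DataFrame, n_bins: int = 7) -> TestResult:
    """Chi-squared goodness of fit of pooled z-scores to a normal distribution.

    Equal-probability bins under the normal fitted to the pooled z-scores;
    df = n_bins - 3 (two estimated moments).  With 7 bins, df = 4.
    """
    if n_bins < 4:
        raise ValueError("need n_bins >= 4")
    if "z" not in table.columns:
        table = zscore_rts(table)
    z = table["z"].to_numpy(float)
    n = len(z)
    expected = n / n_bins
    if expected < 1:
        raise ValueError(f"expected count {expected:.2f} < 1; use fewer bins")
    mu, sd = z.mean(), z.std(ddof=1)
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(z, bins=edges)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = n_bins - 3
    return TestResult(statistic=chi2, df=float(df), p=float(stats.chi2.sf(chi2, df)),
                      name="zscore_normality_chi2")


def syllable_rate(n_syllables: int, duration: float) -> float:
    """Syllabic rate in syllables/second, at 2-decimal reporting precision."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return round(n_syllables / duration, 2)


def epoch_rows(split: GroupSplit, trials: pd.DataFrame, subject, song, condition) -> np.ndarray:
    """Positional rows in an epoch table for one stratum of a split."""
    wanted = set(split.trials_for(subject, song))
    mask = (
        (trials["subject"] == subject)
        & (trials["song"] == song)
        & (trials["condition"] == condition)
        & trials["trial"].isin(wanted)
    )
    return np.flatnonzero(mask.to_numpy())
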