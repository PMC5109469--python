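"""Daily-torpor detection as joint lower outliers from predictive bands.

Torpor is flagged at a time point when the observation falls *strictly below*
the lower bound of the 99.9% posterior predictive band of the animal's own
baseline — jointly for body temperature and oxygen consumption under the
default rule.  Fixed-threshold rules (e.g. T_B < 31 °C) are provided for
comparison with the conventional definitions.  Detection is evaluated on the
days after the baseline training day; missing observations are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExperimentProtocol, MetabolicTimeSeries
from .trend import CircularTrendModel, PredictiveBand, default_sigma2

MODES = ("joint", "tb_only", "vo2_only", "fixed_threshold")


@dataclass
class DetectionRule:
    mode: str = "joint"
    level: float = 0.999
    threshold_tb: float | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if (self.mode == "fixed_threshold") != (self.threshold_tb is not None):
            raise ValueError("threshold_tb is required iff mode='fixed_threshold'")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass
class TorporMask:
    flags: np.ndarray
    rule: DetectionRule
    evaluated_days: tuple

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)


@dataclass
class TorporEpisode:
    """A maximal run of consecutive flagged points."""

    start: float  # minutes
    end: float  # minutes (time stamp of the last flagged bin)
    duration: float  # minutes, end - start + bin_width
    min_tb: float
    vo2_at_min_tb: float


@dataclass
class TorporStats:
    total_torpor_min: float
    n_episodes: int
    mean_episode_min: float
    entered_torpor: bool
    min_tb_overall: float
    vo2_at_min_tb: float


def detect(
    series: MetabolicTimeSeries,
    band_tb: PredictiveBand | None,
    band_vo2: PredictiveBand | None,
    rule: DetectionRule,
    evaluated_days=None,
) -> TorporMask:
    """Flag torpor per time point on the evaluated days (default: days >= 2).

    Joint mode requires both T_B and VO2 strictly below their lower band
    bounds; single-variable modes use one condition; fixed-threshold mode
    compares T_B to the absolute threshold.
    """
    if evaluated_days is None:
        evaluated_days = tuple(range(2, series.D + 1))
    evaluated_days = tuple(np.atleast_1d(evaluated_days).tolist())
    k = series.k_index
    eligible = np.isin(series.day_index, evaluated_days)

    def below(y, band):
        if band is None:
            raise ValueError(f"rule {rule.mode!r} needs a predictive band")
        if band.K != series.K:
            raise ValueError(f"band K={band.K} does not match series K={series.K}")
        with np.errstate(invalid="ignore"):
            return np.isfinite(y) & (y < band.lower[k])

    if rule.mode == "fixed_threshold":
        with np.errstate(invalid="ignore"):
            flags = np.isfinite(series.tb) & (series.tb < rule.threshold_tb)
    elif rule.mode == "tb_only":
        flags = below(series.tb, band_tb)
    elif rule.mode == "vo2_only":
        flags = below(series.vo2, band_vo2)
    else:  # joint
        flags = below(series.tb, band_tb) & below(series.vo2, band_vo2)
    return TorporMask(flags=flags & eligible, rule=rule, evaluated_days=evaluated_days)


def episodes(mask: TorporMask, series: MetabolicTimeSeries) -> list[TorporEpisode]:
    """Maximal consecutive flagged runs with per-episode depth statistics.

    No gap merging and no minimum duration: a single unflagged bin ends an
    episode.
    """
    flags = mask.flags
    if len(flags) != len(series.t):
        raise ValueError("mask length does not match series")
    out = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flags.astype(int), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):  # [i0, i1) flagged
        tb = series.tb[i0:i1]
        if np.all(np.isnan(tb)):
            imin = 0
            min_tb, vo2_at = np.nan, np.nan
        else:
            imin = int(np.nanargmin(tb))
            min_tb = float(tb[imin])
            vo2_at = float(series.vo2[i0 + imin])
        out.append(
            TorporEpisode(
                start=float(series.t[i0]),
                end=float(series.t[i1 - 1]),
                duration=float(series.t[i1 - 1] - series.t[i0] + series.bin_width),
                min_tb=min_tb,
                vo2_at_min_tb=vo2_at,
            )
        )
    return out


def torpor_stats(
    episode_list: list[TorporEpisode],
    series: MetabolicTimeSeries,
    protocol: ExperimentProtocol | None = None,
) -> TorporStats:
    """Aggregate episode statistics for one animal."""
    if not episode_list:
        return TorporStats(
            total_torpor_min=0.0,
            n_episodes=0,
            mean_episode_min=0.0,
            entered_torpor=False,
            min_tb_overall=np.nan,
            vo2_at_min_tb=np.nan,
        )
    durations = [e.duration for e in episode_list]
    deepest = min(
        (e for e in episode_list if np.isfinite(e.min_tb)),
        key=lambda e: e.min_tb,
        default=episode_list[0],
    )
    return TorporStats(
        total_torpor_min=float(np.sum(durations)),
        n_episodes=len(episode_list),
        mean_episode_min=float(np.mean(durations)),
        entered_torpor=True,
        min_tb_overall=deepest.min_tb,
        vo2_at_min_tb=deepest.vo2_at_min_tb,
    )


def induction_rate(stats_list: list[TorporStats]) -> float:
    """Fraction of animals that entered torpor (percent)."""
    if not stats_list:
        raise ValueError("empty cohort")
    return 100.0 * np.mean([s.entered_torpor for s in stats_list])


def minimal_metabolic_point(
    series: MetabolicTimeSeries,
    window,
    mask: TorporMask | None = None,
):
    """The time point minimising T_B within a window, with VO2 read there.

    ``window`` is either a boolean selection array or an inclusive
    ``(t_start, t_end)`` time range in minutes.  With a mask, only flagged
    points are eligible.  Ties break to the earliest time.
    Returns ``(time, min_tb, vo2_at_min_tb)``.
    """
    if isinstance(window, tuple):
        sel = (series.t >= window[0]) & (series.t <= window[1])
    else:
        sel = np.asarray(window, dtype=bool)
        if sel.shape != series.t.shape:
            raise ValueError("boolean window must match the series length")
    if mask is not None:
        sel = sel & mask.flags
    sel = sel & np.isfinite(series.tb)
    if not sel.any():
        raise ValueError("window contains no eligible observed points")
    idx = np.flatnonzero(sel)
    imin = idx[int(np.argmin(series.tb[idx]))]  # np.argmin takes the first tie
    return float(series.t[imin]), float(series.tb[imin]), float(series.vo2[imin])


def dark_phase_window(series: MetabolicTimeSeries, day: int) -> np.ndarray:
    """Boolean window for the dark phase (lights off) of a given day."""
    return (series.day_index == day) & (~series.lights_on)


# ------------------------------------------------------------------ convenience
class TorporDetector:
    """Fits day-1 baselines for both variables and flags torpor afterwards.

    Unlike the array-based estimators, this convenience detector consumes the
    recording object directly: ``fit`` trains the two baseline models on the
    protocol's baseline day, ``predict`` returns the torpor mask for the
    evaluation days.
    """

    def __init__(
        self,
        rule: DetectionRule | None = None,
        sigma2_tb: float | None = None,
        sigma2_vo2: float | None = None,
        n_walkers: int = 8,
        n_warmup: int = 300,
        n_samples: int = 500,
        random_state: int = 0,
    ):
        self.rule = rule or DetectionRule()
        self.sigma2_tb = sigma2_tb
        self.sigma2_vo2 = sigma2_vo2
        self.n_walkers = n_walkers
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, series: MetabolicTimeSeries, baseline_day: int = 1):
        day1 = series.days(baseline_day)
        self.models_ = {}
        self.bands_ = {}
        for i, var in enumerate(("tb", "vo2")):
            sigma2 = (self.sigma2_tb, self.sigma2_vo2)[i]
            if sigma2 is None:
                sigma2 = default_sigma2(var)
            model = CircularTrendModel(
                K=series.K,
                sigma2=sigma2,
                n_walkers=self.n_walkers,
                n_warmup=self.n_warmup,
                n_samples=self.n_samples,
                random_state=self.random_state + i,
            )
            model.fit(day1.k_index, day1.variable(var))
            self.models_[var] = model
            self.bands_[var] = model.predictive_band(self.rule.level)
        self.baseline_day_ = baseline_day
        return self

    def predict(self, series: MetabolicTimeSeries, evaluated_days=None) -> TorporMask:
        return detect(
            series,
            self.bands_["tb"],
            self.bands_["vo2"],
            self.rule,
            evaluated_days=evaluated_days,
        )


def compare_definitions(
    series: MetabolicTimeSeries,
    band_tb: PredictiveBand,
    band_vo2: PredictiveBand,
    thresholds=(31.0, 34.0),
    level: float = 0.999,
) -> pd.DataFrame:
    """Torpor statistics for one animal under the alternative definitions.

    Rows: fixed thresholds, T_B-only outlier, joint (T_B and VO2) outlier —
    the comparison table of torpor definitions.
    """
    rules = [
        DetectionRule(mode="fixed_threshold", threshold_tb=th) for th in thresholds
    ] + [
        DetectionRule(mode="tb_only", level=level),
        DetectionRule(mode="vo2_only", level=level),
        DetectionRule(mode="joint", level=level),
    ]
    rows = []
    for rule in rules:
        mask = detect(series, band_tb, band_vo2, rule)
        stats = torpor_stats(episodes(mask, series), series)
        label = (
            f"tb<{rule.threshold_tb:g}C" if rule.mode == "fixed_threshold"
            else rule.mode
        )
        rows.append(
            {
                "definition": label,
                "total_torpor_min": stats.total_torpor_min,
                "n_episodes": stats.n_episodes,
                "mean_episode_min": stats.mean_episode_min,
                "entered_torpor": stats.entered_torpor,
                "min_tb": stats.min_tb_overall,
                "vo2_at_min_tb": stats.vo2_at_min_tb,
            }
        )
    return pd.DataFrame(rows)
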