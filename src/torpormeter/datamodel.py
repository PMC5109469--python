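"""Core data containers and CSV plumbing for metabolic recordings.

A recording is a regular-grid, multi-day time series of core body temperature
(``tb``, °C) and mass-specific oxygen consumption (``vo2``, ml O2/g/hr) for a
single animal, annotated with ambient temperature (``ta``, °C), light phase and
food availability.  Time is measured in minutes from the start of the
experiment; the experiment starts at lights-on, so zeitgeber time is
``zt = (t / 60) mod 24`` and day boundaries fall on ZT0.

Missing observations are carried as NaN and are never imputed; readers and
writers map empty cells / ``'.'`` to NaN and back.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

#: canonical column order of the recording CSV format
CSV_COLUMNS = ("time_min", "tb_c", "vo2_mlghr", "ta_c", "lights_on", "food_available")

#: default mapping from logical field name to CSV column name
DEFAULT_SCHEMA = {
    "time": "time_min",
    "tb": "tb_c",
    "vo2": "vo2_mlghr",
    "ta": "ta_c",
    "lights_on": "lights_on",
    "food_available": "food_available",
}


class SchemaError(ValueError):
    """A required column is missing or the column mapping is unusable."""


class FormatError(ValueError):
    """The file parses but violates the recording-grid contract."""


@dataclass
class ExperimentProtocol:
    """Fasting-induction protocol: which day is baseline, which day is fasted.

    ``fasting_day`` is the 1-based day on which food is removed at ZT0 and
    returned 24 h later; the standard induction protocol fasts the second
    recorded day.
    """

    ta_target: float = 16.0
    fasting_day: int = 2
    baseline_day: int = 1

    def __post_init__(self) -> None:
        if self.fasting_day <= self.baseline_day:
            raise ValueError(
                f"fasting_day ({self.fasting_day}) must come after "
                f"baseline_day ({self.baseline_day})"
            )


@dataclass
class MetabolicTimeSeries:
    """One animal's multi-day (T_B, VO2) recording on a regular ZT-aligned grid.

    Attributes
    ----------
    t : minutes from experiment start (lights-on of day 1), strictly increasing
        with constant spacing ``bin_width``.
    tb, vo2 : observed series; NaN marks missing points.
    ta : ambient temperature per point (°C).
    lights_on, food_available : boolean annotations per point.
    """

    animal_id: str
    t: np.ndarray
    tb: np.ndarray
    vo2: np.ndarray
    ta: np.ndarray
    lights_on: np.ndarray
    food_available: np.ndarray
    bin_width: int = 6

    # derived, filled by __post_init__
    zt: np.ndarray = field(init=False, repr=False)
    day_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("t", "tb", "vo2", "ta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("lights_on", "food_available"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        self.validate()
        self.zt = (self.t / 60.0) % 24.0
        self.day_index = 1 + np.floor_divide(self.t.astype(int), MINUTES_PER_DAY)

    # ------------------------------------------------------------------ grid
    @property
    def K(self) -> int:
        """Time points per day."""
        return MINUTES_PER_DAY // self.bin_width

    @property
    def D(self) -> int:
        """Number of full recorded days."""
        return len(self.t) // self.K

    @property
    def k_index(self) -> np.ndarray:
        """Time-of-day bin index in [0, K) for every point."""
        return (self.t.astype(int) // self.bin_width) % self.K

    def validate(self) -> None:
        n = len(self.t)
        lengths = {
            len(self.tb), len(self.vo2), len(self.ta),
            len(self.lights_on), len(self.food_available),
        }
        if lengths != {n}:
            raise FormatError("all series must have the same length")
        if n == 0:
            return
        if MINUTES_PER_DAY % self.bin_width != 0:
            raise FormatError(f"bin_width {self.bin_width} does not divide a day")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise FormatError("time stamps must be strictly increasing")
        if np.any(dt != self.bin_width):
            raise FormatError(
                f"irregular time grid: expected spacing {self.bin_width} min"
            )
        if n % self.K != 0:
            raise FormatError(
                f"recording length {n} is not a whole number of days (K={self.K})"
            )
        if np.any(~np.isfinite(self.t)):
            raise FormatError("non-finite time stamps")
        with np.errstate(invalid="ignore"):
            if np.any(self.vo2[np.isfinite(self.vo2)] < 0):
                raise FormatError("vo2 must be non-negative where observed")

    # ------------------------------------------------------------- selection
    def days(self, day_numbers) -> "MetabolicTimeSeries":
        """Sub-series restricted to the given 1-based day numbers."""
        day_numbers = np.atleast_1d(day_numbers)
        sel = np.isin(self.day_index, day_numbers)
        if not sel.any():
            raise ValueError(f"no points on days {list(day_numbers)}")
        return MetabolicTimeSeries(
            animal_id=self.animal_id,
            t=self.t[sel] - (self.t[sel][0] // MINUTES_PER_DAY) * MINUTES_PER_DAY,
            tb=self.tb[sel],
            vo2=self.vo2[sel],
            ta=self.ta[sel],
            lights_on=self.lights_on[sel],
            food_available=self.food_available[sel],
            bin_width=self.bin_width,
        )

    def variable(self, name: str) -> np.ndarray:
        if name not in ("tb", "vo2"):
            raise ValueError(f"unknown variable {name!r} (expected 'tb' or 'vo2')")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.t,
                "tb_c": self.tb,
                "vo2_mlghr": self.vo2,
                "ta_c": self.ta,
                "lights_on": self.lights_on.astype(int),
                "food_available": self.food_available.astype(int),
            }
        )


# ---------------------------------------------------------------------- I/O
def read_recording(path, schema=None, animal_id=None, bin_width=None) -> MetabolicTimeSeries:
    """Read a recording CSV into a validated :class:`MetabolicTimeSeries`.

    ``schema`` maps logical names (``time``, ``tb``, ``vo2``, ``ta``,
    ``lights_on``, ``food_available``) to column names in the file; the default
    is the package's own CSV convention.  Empty cells and ``'.'`` are missing.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     float_precision="round_trip")
    for logical in ("time", "tb", "vo2", "ta"):
        if schema[logical] not in df.columns:
            raise SchemaError(
                f"required column {schema[logical]!r} (for {logical!r}) not found; "
                f"file has {list(df.columns)}"
            )
    t = df[schema["time"]].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) == 0):
        raise FormatError("duplicated time stamps in recording")
    if bin_width is None:
        if len(t) > 1:
            bin_width = int(round(np.min(np.diff(t))))
        else:
            bin_width = 6

    def opt_bool(logical, default):
        col = schema[logical]
        if col in df.columns:
            return df[col].fillna(default).astype(float).astype(bool).to_numpy()
        return np.full(len(t), default, dtype=bool)

    if schema["lights_on"] in df.columns:
        lights = opt_bool("lights_on", True)
    else:  # derive the light phase from ZT: lights on for ZT in [0, 12)
        lights = ((t / 60.0) % 24.0) < 12.0
    return MetabolicTimeSeries(
        animal_id=animal_id or str(path),
        t=t,
        tb=df[schema["tb"]].to_numpy(dtype=float),
        vo2=df[schema["vo2"]].to_numpy(dtype=float),
        ta=df[schema["ta"]].to_numpy(dtype=float),
        lights_on=lights,
        food_available=opt_bool("food_available", True),
        bin_width=bin_width,
    )


def write_recording(series: MetabolicTimeSeries, path) -> None:
    """Write a recording to CSV at full float precision (NaN -> empty cell)."""
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


def bin_series(series: MetabolicTimeSeries, new_bin_width: int) -> MetabolicTimeSeries:
    """Re-bin to a coarser grid by within-bin means over observed points.

    ``new_bin_width`` must be an integer multiple of the current bin width.
    Bins whose input points are all missing stay missing.
    """
    if new_bin_width % series.bin_width != 0:
        raise ValueError(
            f"new bin width {new_bin_width} is not a multiple of {series.bin_width}"
        )
    factor = new_bin_width // series.bin_width
    if factor == 1:
        return replace(series)
    n_new = len(series.t) // factor

    def mean_blocks(x):
        blocks = x[: n_new * factor].reshape(n_new, factor)
        finite = np.isfinite(blocks)
        counts = finite.sum(axis=1)
        sums = np.where(finite, blocks, 0.0).sum(axis=1)
        out = np.full(n_new, np.nan)
        np.divide(sums, counts, out=out, where=counts > 0)
        return out

    def any_blocks(x):
        return x[: n_new * factor].reshape(n_new, factor).any(axis=1)

    return MetabolicTimeSeries(
        animal_id=series.animal_id,
        t=series.t[::factor][:n_new],
        tb=mean_blocks(series.tb),
        vo2=mean_blocks(series.vo2),
        ta=mean_blocks(series.ta),
        lights_on=any_blocks(series.lights_on),
        food_available=any_blocks(series.food_available),
        bin_width=new_bin_width,
    )
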