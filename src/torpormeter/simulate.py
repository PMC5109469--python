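"""Synthetic metabolic recordings with the structure the analysis assumes.

The generator produces per-animal multi-day (T_B, VO2) recordings made of

* a smooth circadian baseline per variable (one baseline per animal, shared
  by all its days, exactly as the fitting model assumes);
* a draw of the circular second-order smoothness prior around that profile,
  with per-step innovation SDs ``sigma2``.  The raw prior is improper and its
  lowest harmonics have enormous variance (growing as the fourth power of the
  period), so the deviation is *anchored* to the profile with scale ``tau``:
  the deviation precision is M/sigma2^2 + I/tau^2.  High-frequency second
  differences keep SD sigma2 while the baseline stays physiological;
  ``tau=None`` gives the exact unanchored prior draw (zero-mean in the
  constant direction);
* Gaussian observation noise ``sigma1``, fresh at every time point;
* fasting-induced torpor bouts simulated mechanistically: within a scheduled
  bout the thermoregulatory regime switches from the normal (G, H, T_R)
  triple to the torpid one and T_B is integrated forward through the heat
  balance dT_B/dt = (H (T_R - T_B) - G (T_B - T_A)) / C, with
  VO2 = max(0, H (T_R - T_B)) plus noise.  Torpor depth therefore scales
  with ambient temperature through the steady state
  (H T_R + G T_A) / (G + H) rather than being pasted in at fixed depth.

Cohort recordings follow the induction protocol: three days, food removed at
ZT0 of day 2 and returned at ZT0 of day 3, constant ambient temperature per
animal.  The cohort circadian profile equals the normal-state steady state
plus a nonnegative activity excess that vanishes once per dark phase, so the
dark-phase minimum of a noise-free animal sits exactly on the steady-state
line that the thermoregulatory analysis fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import MetabolicTimeSeries, MINUTES_PER_DAY
from .thermo import line_params_from_state, steady_state_tb
from .trend import SIGMA2_TB_DEFAULT, SIGMA2_VO2_DEFAULT, _penalty_eig

VARIABLES = ("tb", "vo2")


@dataclass
class SyntheticConfig:
    """Ground-truth parameter set for simulation and recovery testing.

    Tuple-valued fields are (tb, vo2) pairs.  States are (G, H, T_R) triples
    in (ml/g/hr/°C, ml/g/hr/°C, °C); ``C`` is the heat capacity in
    ml O2-equivalent/g/°C (affects transients only, never the steady state).
    """

    seed: int = 0
    n_animals: int = 8
    K: int = 240
    D: int = 3
    bin_width: int = 6
    # plain-cosine circadian profile (used by simulate_baseline_day)
    mesor: tuple = (36.5, 3.5)
    amplitude: tuple = (1.0, 1.0)
    acrophase_zt: tuple = (18.0, 18.0)  # peak in the dark phase
    individual_mesor_sd: tuple = (0.2, 0.15)
    # noise scales
    sigma1: tuple = (0.2, 0.2)
    sigma2: tuple = (SIGMA2_TB_DEFAULT, SIGMA2_VO2_DEFAULT)
    anchor_tau: tuple | None = (0.3, 0.2)
    # thermoregulatory states and heat capacity
    normal_state: tuple = (0.228, 5.1, 36.6)
    torpid_state: tuple = (0.144, 0.437, 32.8)
    C: float = 0.655
    # protocol / cohort structure
    ta_baseline: float = 16.0
    ta_grid: tuple = (8.0, 12.0, 16.0, 20.0, 24.0)
    fasting_day: int = 2
    # cohort circadian structure: steady state + activity excess vanishing at rest_zt
    activity_excess: tuple = (1.2, 1.5)
    rest_zt: float = 18.0
    # torpor bout schedule (uniform ranges, per animal); None disables bouts
    bout_entry_zt: tuple | None = (12.0, 15.0)
    bout_duration_hr: tuple = (5.0, 7.0)
    # minimal-metabolism table noise
    residual_sd_minima: tuple = (0.3, 0.2)
    #: level shift applied to the VO2 series of the model-scale calibration
    #: generator (the fit is level-invariant; the shift keeps the unbounded
    #: Gaussian trend away from the physical zero)
    calibration_vo2_offset: float = 20.0

    def __post_init__(self):
        if any(s < 0 for s in self.sigma1) or any(s < 0 for s in self.sigma2):
            raise ValueError("noise SDs must be non-negative")
        for st in (self.normal_state, self.torpid_state):
            if st[0] <= 0 or st[1] < 0:
                raise ValueError("G must be positive and H non-negative")
        if self.torpid_state[2] > self.normal_state[2]:
            raise ValueError("torpid T_R must not exceed normal T_R")
        if self.K * self.bin_width != MINUTES_PER_DAY:
            raise ValueError("K * bin_width must equal 1440 minutes")

    def rng_for(self, *key) -> np.random.Generator:
        """Deterministic child generator for a named simulation stream."""
        import zlib

        tokens = [zlib.crc32(str(k).encode()) for k in key]
        return np.random.default_rng([self.seed, *tokens])


def _trend_deviation(
    config: SyntheticConfig, vi: int, rng, anchored: bool = False
) -> np.ndarray:
    """One draw of the circular smoothness prior, length K.

    Unanchored (default): an exact draw of the prior with innovation SD
    sigma2, zero-mean in the constant direction — the generative counterpart
    of the fitting model.  Anchored: deviation precision M/sigma2^2 +
    I/tau^2, which pins the baseline near the circadian profile (used by the
    cohort generator, where torpor bouts must ride on a physiological
    baseline); anchoring shrinks the lowest harmonics, so it is *not* used
    when calibrating or recovering sigma2.
    """
    lam, U = _penalty_eig(config.K)
    s2 = config.sigma2[vi]
    if s2 == 0:
        return np.zeros(config.K)
    z = rng.standard_normal(config.K)
    if not anchored or config.anchor_tau is None:
        prec = lam[1:] / s2**2
        return U[:, 1:] @ (z[1:] / np.sqrt(prec))
    tau = config.anchor_tau[vi]
    prec = lam[1:] / s2**2 + 1.0 / tau**2
    return U[:, 1:] @ (z[1:] / np.sqrt(prec))


def _grid(config: SyntheticConfig):
    t = np.arange(config.K * config.D) * config.bin_width
    zt = (t / 60.0) % 24.0
    return t, zt


def _assemble(config, animal_id, t, zt, tb, vo2, ta, fasting=None):
    lights = zt < 12.0
    food = np.ones(len(t), dtype=bool)
    if fasting is not None:
        food[(t // MINUTES_PER_DAY) + 1 == fasting] = False
    return MetabolicTimeSeries(
        animal_id=animal_id,
        t=t,
        tb=tb,
        vo2=vo2,
        ta=np.full(len(t), float(ta)),
        lights_on=lights,
        food_available=food,
        bin_width=config.bin_width,
    )


def simulate_baseline_day(config: SyntheticConfig, animal: int) -> MetabolicTimeSeries:
    """Simulate a D-day torpor-free recording for one animal.

    The animal's baseline is the cosine circadian profile plus one *exact*
    draw of the circular smoothness prior (the generative counterpart of the
    fitting model); all days share it, observation noise is fresh per point.
    Deterministic given (config.seed, animal).

    The exact prior is support-unbounded and its lowest harmonics are very
    diffuse, so simulated trajectories can wander far from the profile; the
    baseline fit is invariant to the level, but to keep the oxygen series in
    the representable (non-negative) range its level is raised by
    ``calibration_vo2_offset``.  Use :func:`simulate_cohort` for
    physiologically-scaled recordings.
    """
    rng = config.rng_for("baseline", animal)
    t, zt = _grid(config)
    k = (t // config.bin_width) % config.K
    values = {}
    for vi, var in enumerate(VARIABLES):
        profile = config.mesor[vi] + config.amplitude[vi] * np.cos(
            2 * np.pi * (np.arange(config.K) * config.bin_width / 60.0
                         - config.acrophase_zt[vi]) / 24.0
        )
        if var == "vo2":
            profile = profile + config.calibration_vo2_offset
        profile = profile + config.individual_mesor_sd[vi] * rng.standard_normal()
        alpha = profile + _trend_deviation(config, vi, rng)
        y = alpha[k] + config.sigma1[vi] * rng.standard_normal(len(t))
        if var == "vo2":
            y = np.clip(y, 0.0, None)
        values[var] = y
    return _assemble(config, f"baseline_a{animal}", t, zt,
                     values["tb"], values["vo2"], config.ta_baseline)


# ------------------------------------------------------------------ torpor bouts
@dataclass
class Bout:
    """A scheduled torpor bout on the fasting day (zeitgeber hours)."""

    entry_zt: float
    duration_hr: float


def _default_bouts(config: SyntheticConfig, rng) -> list[Bout]:
    if config.bout_entry_zt is None:
        return []
    lo, hi = config.bout_entry_zt
    dlo, dhi = config.bout_duration_hr
    return [Bout(entry_zt=rng.uniform(lo, hi), duration_hr=rng.uniform(dlo, dhi))]


def simulate_torpor_bouts(
    series: MetabolicTimeSeries,
    config: SyntheticConfig,
    bouts: list[Bout] | None = None,
    rng: np.random.Generator | None = None,
    return_mask: bool = False,
):
    """Overlay mechanistic torpor bouts on the fasting day of a recording.

    Within each bout the regime is the torpid (G, H, T_R); T_B is integrated
    by explicit stepping at the bin width from the pre-bout observed value.
    After the bout the normal regime drives T_B back up; points are handed
    back to the original series once the rewarming trajectory reaches it.
    """
    fast_days = np.unique(series.day_index[~series.food_available])
    if fast_days.size == 0:
        raise ValueError("series has no fasting day flagged (food_available)")
    fasting_day = int(fast_days[0])
    if rng is None:
        rng = config.rng_for("bouts", series.animal_id)
    if bouts is None:
        bouts = _default_bouts(config, rng)
    day_start = (fasting_day - 1) * MINUTES_PER_DAY
    for b in bouts:
        if not (0.0 <= b.entry_zt and b.entry_zt + b.duration_hr <= 24.0):
            raise ValueError(
                f"bout (entry ZT{b.entry_zt:.1f}, {b.duration_hr:.1f} h) does not "
                "lie within the fasting day"
            )
    tb = series.tb.copy()
    vo2 = series.vo2.copy()
    mask = np.zeros(len(tb), dtype=bool)
    dt_hr = series.bin_width / 60.0
    s_tb, s_vo2 = config.sigma1

    def step(x, state, ta):
        # dT_B/dt = (H (T_R - T_B) - G (T_B - T_A)) / C is linear in T_B;
        # step it with the exact exponential update (unconditionally stable)
        G, H, T_R = state
        rate = (G + H) / config.C
        if rate == 0:
            return x
        target = (H * T_R + G * ta) / (G + H)
        return target + (x - target) * np.exp(-dt_hr * rate)

    for b in sorted(bouts, key=lambda b: b.entry_zt):
        i0 = int(np.searchsorted(series.t, day_start + b.entry_zt * 60.0))
        n_bout = int(round(b.duration_hr * 60.0 / series.bin_width))
        x = tb[i0 - 1] if i0 > 0 else tb[i0]
        if not np.isfinite(x):
            x = steady_state_tb(*config.normal_state, series.ta[i0])
        i = i0
        # torpid phase
        while i < len(tb) and i < i0 + n_bout:
            x = step(x, config.torpid_state, series.ta[i])
            tb[i] = x + s_tb * rng.standard_normal()
            q_in = max(0.0, config.torpid_state[1] * (config.torpid_state[2] - x))
            vo2[i] = max(0.0, q_in + s_vo2 * rng.standard_normal())
            mask[i] = True
            i += 1
        # rewarming under the normal regime; hand back to the baseline series
        # once the trajectory reaches it or closes on the euthermic steady
        # state (the activity-driven baseline can sit above that steady
        # state, and rewarming is a minutes-scale transient, not hours)
        G_n, H_n, TR_n = config.normal_state
        while i < len(tb):
            x = step(x, config.normal_state, series.ta[i])
            target = steady_state_tb(G_n, H_n, TR_n, series.ta[i])
            if (np.isfinite(series.tb[i]) and x >= series.tb[i] - 0.05) \
                    or x >= target - 0.05:
                break
            tb[i] = x + s_tb * rng.standard_normal()
            q_in = max(0.0, config.normal_state[1] * (config.normal_state[2] - x))
            vo2[i] = max(0.0, q_in + s_vo2 * rng.standard_normal())
            i += 1
    out = replace(series, tb=tb, vo2=vo2)
    out.__post_init__()
    return (out, mask) if return_mask else out


# ------------------------------------------------------------------ cohort
def _cohort_baseline(config: SyntheticConfig, animal_id, ta, rng):
    """Torpor-free 3-day recording whose dark-phase minimum sits on the
    normal-state steady-state line (profile = steady state + activity excess)."""
    t, zt = _grid(config)
    k = (t // config.bin_width) % config.K
    zt_k = np.arange(config.K) * config.bin_width / 60.0
    excess_shape = 0.5 * (1.0 - np.cos(2 * np.pi * (zt_k - config.rest_zt) / 24.0))
    G, H, T_R = config.normal_state
    ss_tb = steady_state_tb(G, H, T_R, ta)
    ss_vo2 = max(0.0, H * (T_R - ss_tb))
    values = {}
    for vi, (var, ss) in enumerate(zip(VARIABLES, (ss_tb, ss_vo2))):
        profile = ss + config.activity_excess[vi] * excess_shape
        profile = profile + config.individual_mesor_sd[vi] * rng.standard_normal() \
            * excess_shape  # individual variation in activity, not in the resting point
        alpha = profile + _trend_deviation(config, vi, rng, anchored=True)
        y = alpha[k] + config.sigma1[vi] * rng.standard_normal(len(t))
        if var == "vo2":
            y = np.clip(y, 0.0, None)
        values[var] = y
    return _assemble(config, animal_id, t, zt, values["tb"], values["vo2"], ta,
                     fasting=config.fasting_day)


def simulate_cohort(config: SyntheticConfig):
    """Simulate ``n_animals`` three-day recordings per ambient temperature.

    Returns ``(recordings, true_masks)`` where ``true_masks[i]`` flags the
    scheduled torpid-regime points of ``recordings[i]`` (the detector
    benchmark truth).  Fasting (and hence all bouts) is on ``fasting_day``.
    """
    recordings, masks = [], []
    for ta in config.ta_grid:
        for a in range(config.n_animals):
            aid = f"ta{ta:g}_a{a}"
            rng = config.rng_for("cohort", aid)
            base = _cohort_baseline(config, aid, ta, rng)
            rec, mask = simulate_torpor_bouts(
                base, config, rng=rng, return_mask=True
            )
            recordings.append(rec)
            masks.append(mask)
    return recordings, masks


# ------------------------------------------------------------------ minimal table
def simulate_minimal_table(
    true_params,
    n_per_ta: int,
    residual_sd,
    seed: int = 0,
    ta_grid=(12.0, 16.0, 20.0, 24.0),
    state: str = "normal",
):
    """Simulate a minimal-metabolism table for one state.

    ``true_params`` is either a ``(a1, b1, a2, b2)`` tuple of line parameters
    or a ``(G, H, T_R)`` state triple (inverted through the steady-state
    algebra first).  ``residual_sd`` is a scalar or (tb, vo2) pair.  Rows:
    ``min_tb = a1 T_A + b1 + noise``, ``vo2_at_min = -a2 T_A + b2 + noise``
    (floored at zero).
    """
    import pandas as pd

    residual_sd = np.broadcast_to(np.asarray(residual_sd, dtype=float), (2,))
    if np.any(residual_sd <= 0):
        raise ValueError("residual_sd must be positive")
    true_params = tuple(true_params)
    if len(true_params) == 3:
        a1, b1, a2, b2 = line_params_from_state(*true_params)
    elif len(true_params) == 4:
        a1, b1, a2, b2 = true_params
    else:
        raise ValueError("true_params must be (a1, b1, a2, b2) or (G, H, T_R)")
    rng = np.random.default_rng(seed)
    rows = []
    for ta in ta_grid:
        for a in range(n_per_ta):
            rows.append(
                {
                    "animal_id": f"ta{ta:g}_a{a}",
                    "ta": float(ta),
                    "state": state,
                    "min_tb": a1 * ta + b1 + residual_sd[0] * rng.standard_normal(),
                    "vo2_at_min": max(
                        0.0, -a2 * ta + b2 + residual_sd[1] * rng.standard_normal()
                    ),
                }
            )
    return pd.DataFrame(rows)
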