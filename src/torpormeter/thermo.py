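"""Thermoregulatory parameter estimation from minimal-metabolism tables.

The animal's heat balance at rest is modelled with three parameters: heat
conductance G (heat lost per °C of body-ambient gradient), thermogenesis
feedback gain H (heat produced per °C of set-point deficit) and the set-point
temperature T_R, all heat flows expressed as oxygen-consumption equivalents
(ml O2/g/hr).  At steady state,

    VO2 = G (T_B - T_A)            (conduction law; all consumption offsets loss)
    VO2 = H (T_R - T_B)            (thermogenesis law)
    T_B = (H T_R + G T_A) / (G + H)

The observables are the per-animal minimal metabolic points at a range of
ambient temperatures.  Two Bayesian linear regressions summarise them,

    min T_B  =  a1 T_A + b1 + noise
    min VO2  = -a2 T_A + b2 + noise,

and eliminating T_A identifies the thermogenesis line: H = a2 / a1 and
T_R = b1 + a1 b2 / a2, computed draw-wise from the paired posterior draws.
Conductance G is fitted separately through the no-intercept conduction law.
Slopes and G carry LogNormal(0, 1) priors; intercepts are uniform.

Parameter summaries are posterior means with 89% highest-posterior-density
intervals; Q10 quantifies how much of the metabolic drop exceeds the passive
temperature effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._mcmc import sample_ensemble

#: oxygen-to-energy conversion constants
CAL_PER_ML_O2 = 5.3
JOULE_PER_CAL = 4.184

MINIMAL_TABLE_COLUMNS = ("animal_id", "ta", "state", "min_tb", "vo2_at_min")


# ------------------------------------------------------------------ summaries
def hpdi(draws, mass: float = 0.89):
    """Highest posterior density interval: the shortest contiguous interval of
    sorted draws containing at least ``mass`` of them.

    Ties (several windows of equal width) break toward the earliest window.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HPDI")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize(draws, mass: float = 0.89) -> dict:
    lo, hi = hpdi(draws, mass)
    return {"mean": float(np.mean(draws)), "hpdi_low": lo, "hpdi_high": hi,
            "mass": mass}


# ------------------------------------------------------------------ algebra
def line_params_from_state(G: float, H: float, T_R: float):
    """Invert the steady state: (G, H, T_R) -> (a1, b1, a2, b2)."""
    if G + H <= 0:
        raise ValueError("G + H must be positive")
    a1 = G / (G + H)
    b1 = H * T_R / (G + H)
    a2 = G * H / (G + H)
    b2 = a2 * T_R
    return a1, b1, a2, b2


def state_from_line_params(a1, b1, a2, b2):
    """Recover (G, H, T_R) from the two fitted lines (vectorised over draws)."""
    H = a2 / a1
    T_R = b1 + a1 * b2 / a2
    G = a2 / (1.0 - a1)
    return G, H, T_R


def steady_state_tb(G: float, H: float, T_R: float, T_A: float) -> float:
    """Steady-state body temperature (H T_R + G T_A) / (G + H).

    Perfect insulation (G=0) gives T_R; no thermogenesis (H=0) gives T_A.
    """
    if G + H <= 0:
        raise ValueError("G + H must be positive")
    return (H * T_R + G * T_A) / (G + H)


def q10(vo2_normal, vo2_torpid, tb_normal, tb_torpid):
    """Q10 temperature coefficient of VO2 between normal and torpid states.

    Q10 = (VO2_n / VO2_t) ** (10 / (T_B,n - T_B,t)), evaluated in the log
    domain.  Values well above 2-3 indicate active metabolic suppression
    beyond the passive temperature effect.
    """
    if vo2_normal <= 0 or vo2_torpid <= 0:
        raise ValueError("oxygen consumption rates must be positive")
    dt = tb_normal - tb_torpid
    if dt == 0:
        raise ValueError("Q10 undefined for zero temperature difference")
    value = float(np.exp((10.0 / dt) * (np.log(vo2_normal) - np.log(vo2_torpid))))
    return Q10Result(
        q10=value,
        inputs={"vo2_normal": vo2_normal, "vo2_torpid": vo2_torpid,
                "tb_normal": tb_normal, "tb_torpid": tb_torpid},
    )


def o2_to_energy(ml_o2: float):
    """Convert an oxygen volume to energy: (calories, joules)."""
    if ml_o2 < 0:
        raise ValueError("oxygen volume must be non-negative")
    cal = CAL_PER_ML_O2 * ml_o2
    return cal, JOULE_PER_CAL * cal


@dataclass
class Q10Result:
    q10: float
    inputs: dict
    ta: float | None = None


# ------------------------------------------------------------------ posteriors
@dataclass
class LinearFitPosterior:
    """Draws of one minimal-metabolism regression.

    ``sign_convention`` records whether the model was y = +slope*T_A + b
    (body temperature, slope a1) or y = -slope*T_A + b (oxygen consumption,
    slope a2); slope draws are positive by prior in both cases.
    """

    slope_draws: np.ndarray
    intercept_draws: np.ndarray
    residual_sd_draws: np.ndarray
    sign_convention: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def sign(self) -> float:
        return 1.0 if self.sign_convention == "+slope*TA" else -1.0

    def predict_mean(self, ta):
        return float(np.mean(self.slope_draws)) * self.sign * np.asarray(ta) \
            + float(np.mean(self.intercept_draws))


@dataclass
class ConductancePosterior:
    g_draws: np.ndarray
    residual_sd_draws: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def g_mean(self) -> float:
        return float(np.mean(self.g_draws))


@dataclass
class ThermoDerived:
    """Derived thermogenesis parameters with HPDI summaries."""

    h_draws: np.ndarray
    tr_draws: np.ndarray
    gh_ratio_draws: np.ndarray | None = None
    summaries: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.summaries:
            self.summaries = {
                "H": summarize(self.h_draws),
                "T_R": summarize(self.tr_draws),
            }
            if self.gh_ratio_draws is not None:
                self.summaries["G_over_H"] = summarize(self.gh_ratio_draws)


# ------------------------------------------------------------------ estimators
class BayesianLine(BaseEstimator):
    """Bayesian simple linear regression with a positive slope magnitude.

    Model: y = slope_sign * a * x + b + Normal(0, sigma) with
    a ~ LogNormal(0, 1), b ~ Uniform(-intercept_bound, intercept_bound),
    sigma ~ Uniform(0, sigma_bound).  Fitted attributes: ``slope_draws_``
    (positive magnitude a), ``intercept_draws_``, ``sigma_draws_``,
    ``rhat_``, ``ess_``.
    """

    def __init__(
        self,
        slope_sign=1,
        intercept_bound=1000.0,
        sigma_bound=100.0,
        n_walkers=16,
        n_warmup=400,
        n_samples=250,
        random_state=0,
    ):
        self.slope_sign = slope_sign
        self.intercept_bound = intercept_bound
        self.sigma_bound = sigma_bound
        self.n_walkers = n_walkers
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(len(y), -1)[:, 0]
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if np.unique(x).size < 3:
            raise ValueError("need at least 3 distinct predictor values")
        sign = float(self.slope_sign)

        def log_post(theta):
            la, b, ls = theta
            sig = np.exp(ls)
            if not (0 < sig < self.sigma_bound) or abs(b) >= self.intercept_bound:
                return -np.inf
            a = np.exp(la)
            resid = y - (sign * a * x + b)
            ll = -y.size * ls - 0.5 * np.sum(resid**2) / sig**2
            return ll - 0.5 * la**2 + ls  # LogNormal(0,1) on a; Jacobian for sigma

        # initialise at the least-squares solution (slope folded to positive)
        A = np.vstack([x, np.ones_like(x)]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a0 = max(abs(coef[0]), 1e-6)
        b0 = coef[1] if sign * coef[0] >= 0 else float(np.mean(y))
        resid0 = y - (sign * a0 * x + b0)
        s0 = max(float(np.std(resid0)), 1e-3)
        res = sample_ensemble(
            log_post,
            [np.log(a0), b0, np.log(s0)],
            self.n_walkers, self.n_warmup, self.n_samples,
            np.random.default_rng(self.random_state),
        )
        self.slope_draws_ = np.exp(res["draws"][:, 0])
        self.intercept_draws_ = res["draws"][:, 1]
        self.sigma_draws_ = np.exp(res["draws"][:, 2])
        self.rhat_ = res["rhat"]
        self.ess_ = res["ess"]
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return float(self.slope_draws_.mean()) * self.slope_sign * x \
            + float(self.intercept_draws_.mean())

    def posterior(self) -> LinearFitPosterior:
        return LinearFitPosterior(
            slope_draws=self.slope_draws_,
            intercept_draws=self.intercept_draws_,
            residual_sd_draws=self.sigma_draws_,
            sign_convention="+slope*TA" if self.slope_sign > 0 else "-slope*TA",
            diagnostics={"rhat": self.rhat_, "ess": self.ess_},
        )


class ConductanceModel(BaseEstimator):
    """No-intercept Bayesian fit of the conduction law VO2 = G (T_B - T_A).

    G ~ LogNormal(0, 1), sigma ~ Uniform(0, sigma_bound).  Rows with a
    non-positive temperature gradient are excluded with a warning (the
    conduction law presumes T_B > T_A).
    """

    def __init__(
        self,
        sigma_bound=100.0,
        n_walkers=16,
        n_warmup=400,
        n_samples=250,
        random_state=0,
    ):
        self.sigma_bound = sigma_bound
        self.n_walkers = n_walkers
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(len(y), -1)[:, 0]
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        bad = x <= 0
        if bad.any():
            warnings.warn(
                f"excluding {int(bad.sum())} row(s) with non-positive "
                "temperature gradient from the conductance fit",
                stacklevel=2,
            )
            x, y = x[~bad], y[~bad]
        if x.size < 2:
            raise ValueError("need at least 2 rows with positive gradient")

        def log_post(theta):
            lg, ls = theta
            sig = np.exp(ls)
            if not 0 < sig < self.sigma_bound:
                return -np.inf
            resid = y - np.exp(lg) * x
            ll = -y.size * ls - 0.5 * np.sum(resid**2) / sig**2
            return ll - 0.5 * lg**2 + ls

        g0 = max(float((x @ y) / (x @ x)), 1e-6)
        s0 = max(float(np.std(y - g0 * x)), 1e-3)
        res = sample_ensemble(
            log_post,
            [np.log(g0), np.log(s0)],
            self.n_walkers, self.n_warmup, self.n_samples,
            np.random.default_rng(self.random_state),
        )
        self.g_draws_ = np.exp(res["draws"][:, 0])
        self.sigma_draws_ = np.exp(res["draws"][:, 1])
        self.rhat_ = res["rhat"]
        self.ess_ = res["ess"]
        return self

    def predict(self, X):
        return float(self.g_draws_.mean()) * np.asarray(X, dtype=float).reshape(-1)

    def posterior(self) -> ConductancePosterior:
        return ConductancePosterior(
            g_draws=self.g_draws_,
            residual_sd_draws=self.sigma_draws_,
            diagnostics={"rhat": self.rhat_, "ess": self.ess_},
        )


# ------------------------------------------------------------------ wrappers
def _state_rows(table: pd.DataFrame, state: str | None):
    if state is not None:
        table = table[table["state"] == state]
    if table.empty:
        raise ValueError(f"no rows for state {state!r}")
    return table


def fit_tb_regression(table: pd.DataFrame, state=None, **kwargs) -> LinearFitPosterior:
    """Fit min T_B = a1 T_A + b1 to the minimal-metabolism rows of one state."""
    rows = _state_rows(table, state)
    model = BayesianLine(slope_sign=+1, **kwargs)
    model.fit(rows[["ta"]].to_numpy(), rows["min_tb"].to_numpy())
    return model.posterior()


def fit_vo2_regression(table: pd.DataFrame, state=None, **kwargs) -> LinearFitPosterior:
    """Fit min VO2 = -a2 T_A + b2 to the minimal-metabolism rows of one state."""
    rows = _state_rows(table, state)
    model = BayesianLine(slope_sign=-1, **kwargs)
    model.fit(rows[["ta"]].to_numpy(), rows["vo2_at_min"].to_numpy())
    return model.posterior()


def fit_conductance(table: pd.DataFrame, state=None, **kwargs) -> ConductancePosterior:
    """No-intercept conduction-law fit on (T_B - T_A, VO2) pairs of one state."""
    rows = _state_rows(table, state)
    grad = rows["min_tb"].to_numpy() - rows["ta"].to_numpy()
    model = ConductanceModel(**kwargs)
    model.fit(grad.reshape(-1, 1), rows["vo2_at_min"].to_numpy())
    return model.posterior()


def _check_paired(fit_tb: LinearFitPosterior, fit_vo2: LinearFitPosterior):
    if fit_tb.slope_draws.size != fit_vo2.slope_draws.size:
        raise ValueError("posterior draw counts differ; cannot pair draw-wise")


def derive_H(fit_tb: LinearFitPosterior, fit_vo2: LinearFitPosterior) -> np.ndarray:
    """Feedback gain H = a2 / a1, paired draw-wise."""
    _check_paired(fit_tb, fit_vo2)
    return fit_vo2.slope_draws / fit_tb.slope_draws


def derive_TR(fit_tb: LinearFitPosterior, fit_vo2: LinearFitPosterior) -> np.ndarray:
    """Set-point T_R = b1 + a1 b2 / a2, paired draw-wise."""
    _check_paired(fit_tb, fit_vo2)
    return fit_tb.intercept_draws + fit_tb.slope_draws * fit_vo2.intercept_draws \
        / fit_vo2.slope_draws


def derive_thermo(
    fit_tb: LinearFitPosterior,
    fit_vo2: LinearFitPosterior,
    conductance: ConductancePosterior | None = None,
) -> ThermoDerived:
    h = derive_H(fit_tb, fit_vo2)
    tr = derive_TR(fit_tb, fit_vo2)
    gh = None
    if conductance is not None and conductance.g_draws.size == h.size:
        gh = conductance.g_draws / h
    return ThermoDerived(h_draws=h, tr_draws=tr, gh_ratio_draws=gh)


# ------------------------------------------------------------------ checks / reports
@dataclass
class ExceedanceReport:
    """Posterior predictive check of a group mean against a fitted line."""

    ta_probe: float
    n_new: int
    observed_mean: float
    predicted_mean: float
    hpdi_low: float
    hpdi_high: float

    @property
    def exceeds_upper(self) -> bool:
        return self.observed_mean > self.hpdi_high

    @property
    def below_lower(self) -> bool:
        return self.observed_mean < self.hpdi_low


def predictive_check_low_ta(
    fit: LinearFitPosterior,
    ta_probe: float,
    n_new: int,
    observed_mean: float,
    mass: float = 0.89,
    random_state: int = 0,
) -> ExceedanceReport:
    """Check whether an observed group mean at a probe ambient temperature is
    outside the HPDI of the predicted mean of ``n_new`` new observations.

    Per posterior draw, the mean of n_new new points at ta_probe is
    Normal(linear predictor, sigma^2 / n_new); one sample per draw gives the
    predictive distribution of the group mean.
    """
    if n_new < 1:
        raise ValueError("n_new must be at least 1")
    rng = np.random.default_rng(random_state)
    mu = fit.sign * fit.slope_draws * ta_probe + fit.intercept_draws
    samples = mu + fit.residual_sd_draws / np.sqrt(n_new) \
        * rng.standard_normal(mu.size)
    lo, hi = hpdi(samples, mass)
    return ExceedanceReport(
        ta_probe=ta_probe,
        n_new=n_new,
        observed_mean=float(observed_mean),
        predicted_mean=float(np.mean(mu)),
        hpdi_low=lo,
        hpdi_high=hi,
    )


def summarize_state_shift(
    normal: ThermoDerived,
    torpid: ThermoDerived,
    g_normal: ConductancePosterior,
    g_torpid: ConductancePosterior,
) -> dict:
    """Percent changes of the posterior-mean parameters between states.

    Percent reductions use ratios of posterior means (difference of posterior
    means equals the posterior mean of the paired difference; the ratio
    summaries do not commute the same way, so the geometric-mean ratio of H
    is reported alongside for paired draws).
    """
    gn, gt = g_normal.g_mean, g_torpid.g_mean
    hn = float(np.mean(normal.h_draws))
    ht = float(np.mean(torpid.h_draws))
    trn = float(np.mean(normal.tr_draws))
    trt = float(np.mean(torpid.tr_draws))
    out = {
        "g_normal": gn,
        "g_torpid": gt,
        "g_reduction_pct": 100.0 * (1.0 - gt / gn),
        "h_normal": hn,
        "h_torpid": ht,
        "h_reduction_pct": 100.0 * (1.0 - ht / hn),
        "h_difference": hn - ht,
        "tr_normal": trn,
        "tr_torpid": trt,
        "tr_difference": trn - trt,
        "gh_normal": gn / hn,
        "gh_torpid": gt / ht,
    }
    if normal.h_draws.size == torpid.h_draws.size:
        out["h_ratio_geometric"] = float(
            np.exp(np.mean(np.log(torpid.h_draws) - np.log(normal.h_draws)))
        )
    return out


def group_minimal_means(table: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean minimal T_B and VO2 per (state, T_A)."""
    return (
        table.groupby(["state", "ta"])[["min_tb", "vo2_at_min"]]
        .mean()
        .reset_index()
    )


def q10_by_ta(table: pd.DataFrame) -> list[Q10Result]:
    """Q10 per ambient temperature from group-level mean minima.

    Uses the mean normal and torpid minimal points at each T_A that has both
    states observed.
    """
    means = group_minimal_means(table)
    out = []
    for ta in sorted(means["ta"].unique()):
        sub = means[means["ta"] == ta].set_index("state")
        if {"normal", "torpid"} <= set(sub.index):
            r = q10(
                sub.loc["normal", "vo2_at_min"],
                sub.loc["torpid", "vo2_at_min"],
                sub.loc["normal", "min_tb"],
                sub.loc["torpid", "min_tb"],
            )
            r.ta = float(ta)
            out.append(r)
    return out


def q10_per_animal(table: pd.DataFrame) -> list[Q10Result]:
    """Per-animal Q10 where an animal has both a normal and a torpid row."""
    out = []
    for (aid, ta), sub in table.groupby(["animal_id", "ta"]):
        sub = sub.set_index("state")
        if {"normal", "torpid"} <= set(sub.index):
            r = q10(
                sub.loc["normal", "vo2_at_min"],
                sub.loc["torpid", "vo2_at_min"],
                sub.loc["normal", "min_tb"],
                sub.loc["torpid", "min_tb"],
            )
            r.ta = float(ta)
            out.append(r)
    return out
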