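"""Synthetic observers: simulate complete sessions from a parameterized model.

Every downstream stage (behavioural summaries, model fitting, model
comparison) is exercised on sessions produced here, since no participant
data are available. Estimation responses follow the generative observer
models exactly; detection, hallucinations and reaction times follow simple
descriptive emulations (a logistic psychometric function of log-luminance,
a prior-weighted hallucination mixture, a lognormal RT) whose only job is
to give the behavioural summaries realistic material to chew on — none of
them is a fitted or theoretically claimed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    AddParams,
    BayesParams,
    _percept_map,
    grid_angles,
    kappa_from_sigma,
    wrap_deg,
)
from .task import RANDOM_DIRECTION, StaircaseState, TrialSchedule, staircase_update

__all__ = ["DetectionConfig", "TimingConfig", "SessionData", "simulate_session"]

SESSION_COLUMNS = ["trial_index", "condition", "direction_deg", "luminance",
                   "detected", "estimate_deg", "rt_s", "observer_id", "seed"]


@dataclass(frozen=True)
class DetectionConfig:
    """Descriptive detection model: logistic in log-luminance.

    ``threshold`` is the luminance (cd/m^2 above background) of 50%
    detection; ``slope`` the logistic steepness per log-unit.
    ``direction_boost`` multiplies the detection odds at the over-
    represented +/-32 deg directions, emulating better detection at
    expected directions. ``false_alarm_rate`` is the hallucination
    probability on zero-contrast trials and
    ``hallucination_prior_weight`` the probability such a hallucinated
    direction is drawn from the acquired prior rather than uniformly.
    """

    threshold: float = 0.1
    slope: float = 2.5
    direction_boost: float = 1.5
    false_alarm_rate: float = 0.15
    hallucination_prior_weight: float = 0.7

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        for p in (self.false_alarm_rate, self.hallucination_prior_weight):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.threshold <= 0 or self.direction_boost <= 0:
            raise ValueError("threshold and direction_boost must be positive")

    def p_detect(self, luminance: float, direction_deg: float | None) -> float:
        logit = self.slope * (np.log(luminance) - np.log(self.threshold))
        if direction_deg is not None and abs(abs(wrap_deg(direction_deg)) - 32.0) < 8.0:
            logit += np.log(self.direction_boost)
        return float(1.0 / (1.0 + np.exp(-logit)))


@dataclass(frozen=True)
class TimingConfig:
    """Descriptive reaction-time / omission model.

    RTs are lognormal with log-mean ``rt_log_mean`` (log seconds) and
    log-sd ``rt_log_sd``; the log-mean shifts by ``rt_shift_32`` at the
    expected +/-32 deg directions. ``omission_rate`` is the chance a trial
    produces no estimate within the response window.
    """

    rt_log_mean: float = 0.0
    rt_log_sd: float = 0.3
    rt_shift_32: float = -0.1
    omission_rate: float = 0.02

    def __post_init__(self):
        if self.rt_log_sd <= 0:
            raise ValueError("rt_log_sd must be positive")
        if not 0.0 <= self.omission_rate <= 1.0:
            raise ValueError("omission_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SessionData:
    """Per-trial stimuli and responses for one simulated (or loaded) session.

    The table has one row per trial with columns ``trial_index``,
    ``condition``, ``direction_deg`` (NaN on zero-contrast trials),
    ``luminance``, ``detected``, ``estimate_deg`` (NaN if no response),
    ``rt_s``, ``observer_id`` and ``seed``. Angles are degrees in
    ``[-180, 180)``; times are seconds.
    """

    df: pd.DataFrame
    observer_id: str = "obs0"
    seed: int = 0

    def __post_init__(self):
        missing = [c for c in SESSION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"session table missing columns: {missing}")
        zero = self.df["condition"] == "zero"
        if zero.any() and self.df.loc[zero, "direction_deg"].notna().any():
            raise ValueError("zero-contrast trials must have no direction")
        est = self.df["estimate_deg"].dropna()
        if len(est) and ((est < -180).any() or (est >= 180).any()):
            raise ValueError("estimates must lie in [-180, 180)")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "SessionData":
        df = pd.read_csv(path)
        missing = [c for c in SESSION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: malformed session CSV, missing {missing}")
        df["detected"] = df["detected"].astype(bool)
        obs = str(df["observer_id"].iloc[0]) if len(df) else "obs0"
        seed = int(df["seed"].iloc[0]) if len(df) else 0
        return cls(df=df, observer_id=obs, seed=seed)


def _vm_draw(rng, mu_deg, sigma_deg):
    return wrap_deg(np.rad2deg(
        rng.vonmises(np.deg2rad(mu_deg), kappa_from_sigma(sigma_deg))))


def _prior_draw(rng, theta_p, sigma_p):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return _vm_draw(rng, sign * theta_p, sigma_p)


class _PerceptInterp:
    """Circularly interpolated percept map theta_s -> theta_perc."""

    def __init__(self, sigma_s: float, params: BayesParams):
        grid = grid_angles()
        mu = _percept_map(sigma_s, params, grid)
        z = np.exp(1j * np.deg2rad(mu))
        self._x = np.concatenate([grid, [180.0]])
        self._re = np.concatenate([z.real, [z.real[0]]])
        self._im = np.concatenate([z.imag, [z.imag[0]]])

    def __call__(self, theta_s: float) -> float:
        x = wrap_deg(theta_s)
        re = np.interp(x, self._x, self._re)
        im = np.interp(x, self._x, self._im)
        return float(np.rad2deg(np.arctan2(im, re)))


def _estimate_bayes(rng, theta_act, params: BayesParams, variant: str,
                    interps: dict, *, veridical: bool = False) -> float:
    """One estimation response. ``veridical`` trials (high contrast) skip
    the sensory/prior stage: the percept is the true direction, so their
    errors reflect motor noise (plus lapses) only."""
    sigma_s = params.sigma_s_for(theta_act, variant)
    if rng.random() < params.alpha_p:  # lapse
        if variant == "BAYES":
            perc = float(rng.uniform(-180.0, 180.0))
        else:
            perc = _prior_draw(rng, params.theta_p, params.sigma_p)
    elif veridical:
        perc = theta_act
    else:
        theta_s = _vm_draw(rng, theta_act, sigma_s)
        if sigma_s not in interps:
            interps[sigma_s] = _PerceptInterp(sigma_s, params)
        perc = interps[sigma_s](theta_s)
    return _vm_draw(rng, perc, params.sigma_m)


def _estimate_add(rng, theta_act, params: AddParams, variant: str) -> float:
    if rng.random() < params.alpha_p:  # lapse
        if variant.endswith("_u"):
            perc = float(rng.uniform(-180.0, 180.0))
        else:
            perc = _prior_draw(rng, params.theta_p, params.sigma_p)
    elif rng.random() < params.w_prior:  # prior route
        if "sample" in variant:
            perc = _prior_draw(rng, params.theta_p, params.sigma_p)
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            perc = sign * params.theta_p
    else:  # likelihood route
        perc = _vm_draw(rng, theta_act, params.sigma_s)
    return _vm_draw(rng, perc, params.sigma_m)


def simulate_session(schedule: TrialSchedule,
                     params: BayesParams | AddParams,
                     det: DetectionConfig | None = None,
                     seed: int = 0,
                     *,
                     variant: str | None = None,
                     timing: TimingConfig | None = None,
                     observer_id: str = "obs0") -> SessionData:
    """Simulate one full session on a trial schedule.

    Low-contrast stimulus trials: the estimate follows the generative
    observer model; high-contrast trials are treated as veridical (percept
    equals the true direction, so errors carry motor noise and lapses
    only — the premise under which motor noise is estimated from them).
    Detection follows :class:`DetectionConfig` on the trial's luminance,
    and the two low-contrast staircases are advanced trial by trial from
    the detection outcomes. Zero-contrast trials: detection occurs at the
    false-alarm rate, and a detected ("hallucination") trial yields an
    estimate drawn from the prior-or-uniform mixture plus motor noise.
    Estimates are omitted at the configured omission rate, emulating the
    finite response window; RTs are lognormal with a mean reduction at the
    expected directions.

    Deterministic for fixed inputs and ``seed``.
    """
    det = det or DetectionConfig()
    timing = timing or TimingConfig()
    if variant is None:
        variant = "ADD_sample_p" if isinstance(params, AddParams) else "BAYES_P"
    is_add = isinstance(params, AddParams)
    if is_add and not variant.startswith("ADD"):
        raise ValueError(f"variant {variant!r} does not match AddParams")
    if not is_add and variant.startswith("ADD"):
        raise ValueError(f"variant {variant!r} requires AddParams")

    rng = np.random.default_rng(seed)
    cfg = schedule.design
    stairs = {
        "low_2_1": StaircaseState(rule="two_up_one_down",
                                  current_level=cfg.staircase_start,
                                  factor=cfg.staircase_factor,
                                  bounds=cfg.luminance_bounds),
        "low_4_1": StaircaseState(rule="four_up_one_down",
                                  current_level=cfg.staircase_start,
                                  factor=cfg.staircase_factor,
                                  bounds=cfg.luminance_bounds),
    }
    interps: dict = {}
    rows = []
    for t in schedule.trials:
        direction = np.nan
        luminance = np.nan
        estimate = np.nan
        rt = np.nan
        if t.condition == "zero":
            detected = rng.random() < det.false_alarm_rate
            if detected:
                if rng.random() < det.hallucination_prior_weight:
                    perc = _prior_draw(rng, params.theta_p, params.sigma_p)
                else:
                    perc = float(rng.uniform(-180.0, 180.0))
                estimate = _vm_draw(rng, perc, params.sigma_m)
                rt = float(rng.lognormal(timing.rt_log_mean, timing.rt_log_sd))
        else:
            if t.direction_deg == RANDOM_DIRECTION:
                direction = float(rng.uniform(-180.0, 180.0))
            else:
                direction = float(t.direction_deg)
            if t.condition == "high":
                luminance = cfg.high_luminance
            else:
                luminance = stairs[t.condition].current_level
            detected = rng.random() < det.p_detect(luminance, direction)
            if t.condition in stairs:
                stairs[t.condition] = staircase_update(stairs[t.condition], detected)
            if is_add:
                estimate = _estimate_add(rng, direction, params, variant)
            else:
                estimate = _estimate_bayes(rng, direction, params, variant,
                                           interps,
                                           veridical=(t.condition == "high"))
            at32 = abs(abs(direction) - 32.0) < 8.0
            mu = timing.rt_log_mean + (timing.rt_shift_32 if at32 else 0.0)
            rt = float(rng.lognormal(mu, timing.rt_log_sd))
            if rng.random() < timing.omission_rate:
                estimate = np.nan
                rt = np.nan
        rows.append({"trial_index": t.index, "condition": t.condition,
                     "direction_deg": direction, "luminance": luminance,
                     "detected": bool(detected), "estimate_deg": estimate,
                     "rt_s": rt, "observer_id": observer_id, "seed": seed})
    return SessionData(df=pd.DataFrame(rows), observer_id=observer_id, seed=seed)
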