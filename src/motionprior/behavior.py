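"""Behavioural summary statistics for estimation/detection sessions.

Covers session-level quality control, the von-Mises-plus-uniform mixture
fit used for per-direction bias/variability/lapse estimates, descriptive
detection and reaction-time summaries, the hallucination probability ratio
on no-stimulus trials, and windowed learning-dynamics series.

Conventions: all angles in degrees; estimation errors are wrapped to
``[-180, 180)``; per-direction statistics are computed on low-contrast
trials only, restricted to trials where an estimate was made and the
observer reported seeing the stimulus; negative directions are folded onto
positive magnitudes with the error sign mirrored, so a positive bias means
displacement toward the +/-32 deg prior modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import DIRECTION_MAGNITUDES, circ_mean_deg, vm_density, wrap_deg
from .simulate import SessionData

__all__ = [
    "QCConfig",
    "QCReport",
    "VmMixtureFit",
    "PRatioResult",
    "qc_filter",
    "fit_vm_mixture",
    "direction_stats",
    "p_ratio",
    "learning_dynamics",
]

#: minimum usable trials for a per-stratum mixture fit
MIN_STRATUM_TRIALS = 10


@dataclass(frozen=True)
class QCConfig:
    """Inclusion thresholds: high-contrast detection must exceed
    ``min_detection_high``, high-contrast circular RMSE of estimation
    error must be below ``max_rmse_deg``, and low-contrast detection must
    reach at least ``min_detection_low``."""

    min_detection_high: float = 0.70
    max_rmse_deg: float = 30.0
    min_detection_low: float = 0.50


@dataclass(frozen=True)
class QCReport:
    detection_high: float
    rmse_high_deg: float
    detection_low: float
    pass_detection_high: bool
    pass_rmse: bool
    pass_detection_low: bool

    @property
    def passed(self) -> bool:
        return self.pass_detection_high and self.pass_rmse and self.pass_detection_low


@dataclass(frozen=True)
class VmMixtureFit:
    """MLE of the von-Mises-plus-uniform response-error mixture
    ``(1 - alpha) V(mu, sigma) + alpha / 360`` (densities per degree)."""

    mu: float
    sigma: float
    alpha: float
    log_likelihood: float
    n_trials: int
    converged: bool


@dataclass(frozen=True)
class PRatioResult:
    """Hallucination probability ratio.

    ``p_ratio`` is the average probability of a no-stimulus estimate
    falling in one of the two 32-deg-wide bins centred on the prior modes
    (+/-32 deg), multiplied by the number of bins; 1 under uniform
    responding. ``defined`` is False when no hallucination estimates exist
    (the ratio is then NaN, not 0).
    """

    p_ratio: float
    n_hallucinations: int
    n_bins: int
    defined: bool


def estimation_errors(df: pd.DataFrame) -> np.ndarray:
    """Wrapped estimate-minus-direction errors for rows that have both."""
    ok = df["estimate_deg"].notna() & df["direction_deg"].notna()
    sub = df.loc[ok]
    return wrap_deg(sub["estimate_deg"].to_numpy() - sub["direction_deg"].to_numpy())


def circular_rmse(errors_deg) -> float:
    e = wrap_deg(np.asarray(errors_deg, dtype=float))
    return float(np.sqrt(np.mean(e**2)))


def qc_filter(session: SessionData, thresholds: QCConfig | None = None) -> QCReport:
    """Session inclusion check on detection performance and high-contrast
    estimation accuracy. Raises ``ValueError`` if a needed condition
    stratum is empty."""
    thresholds = thresholds or QCConfig()
    df = session.df
    high = df[df["condition"] == "high"]
    low = df[df["condition"].isin(["low_2_1", "low_4_1"])]
    if high.empty or low.empty:
        raise ValueError("session lacks high- or low-contrast trials")
    det_high = float(high["detected"].mean())
    det_low = float(low["detected"].mean())
    err = estimation_errors(high)
    if err.size == 0:
        raise ValueError("no high-contrast estimation responses")
    rmse = circular_rmse(err)
    return QCReport(
        detection_high=det_high,
        rmse_high_deg=rmse,
        detection_low=det_low,
        pass_detection_high=det_high > thresholds.min_detection_high,
        pass_rmse=rmse < thresholds.max_rmse_deg,
        pass_detection_low=det_low >= thresholds.min_detection_low,
    )


_SIGMA_BOUNDS = (0.5, 120.0)


def _mixture_nll(theta, errors):
    mu, sigma, alpha = theta
    dens = (1.0 - alpha) * vm_density(errors, mu, sigma) + alpha / 360.0
    return -np.sum(np.log(np.maximum(dens, 1e-300)))


def fit_vm_mixture(errors) -> VmMixtureFit:
    """Fit the error mixture by bounded multi-start maximum likelihood.

    Deterministic: a fixed 9-point start grid (the circular mean of the
    data crossed with three widths and three lapse levels) is polished by
    L-BFGS-B under bounds mu in [-180, 180], sigma in [0.5, 120],
    alpha in [0, 1].
    """
    e = wrap_deg(np.asarray(errors, dtype=float))
    e = e[np.isfinite(e)]
    if e.size < MIN_STRATUM_TRIALS:
        raise ValueError(f"need >= {MIN_STRATUM_TRIALS} observations, got {e.size}")
    try:
        mu0 = circ_mean_deg(e)
    except FloatingPointError:
        mu0 = 0.0
    starts = [(mu0, s, a) for s in (10.0, 30.0, 80.0) for a in (0.02, 0.3, 0.8)]
    bounds = [(-180.0, 180.0), _SIGMA_BOUNDS, (0.0, 1.0)]
    best = None
    for x0 in starts:
        res = minimize(_mixture_nll, x0, args=(e,), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("mixture fit failed at every start")
    mu, sigma, alpha = best.x
    return VmMixtureFit(mu=float(wrap_deg(mu)), sigma=float(sigma),
                        alpha=float(alpha), log_likelihood=float(-best.fun),
                        n_trials=int(e.size), converged=bool(best.success))


def _usable_low(df: pd.DataFrame) -> pd.DataFrame:
    low = df[df["condition"].isin(["low_2_1", "low_4_1"])]
    return low[low["detected"] & low["estimate_deg"].notna()
               & low["direction_deg"].notna()]


def _is_predetermined(direction: np.ndarray) -> np.ndarray:
    mags = np.abs(wrap_deg(direction))
    return np.isin(np.round(mags).astype(int), [0, 16, 32, 48, 64])


def direction_stats(session: SessionData) -> pd.DataFrame:
    """Per-direction-magnitude bias, variability, lapse, RT and detection.

    Low-contrast trials only; estimation statistics use trials with a
    response and a "seen" report; random-direction trials are excluded.
    Folding: errors at negative directions are sign-flipped; the 0-deg
    stratum (where "toward the modes" has no sign) is symmetrized by
    pooling each error with its mirror image, which makes the output
    invariant under mirroring the whole session.

    Returns one row per magnitude {0, 16, 32, 48, 64} with columns
    ``magnitude, n_est, bias_deg`` (folded location minus true magnitude,
    positive = displaced to larger angles), ``bias_toward_mode_deg``
    (same displacement signed positive toward the nearest +/-32 mode;
    undefined at 0 and 32), ``sigma_deg, alpha, mean_rt_s,
    detection_frac, fitted``; strata below the minimum trial count carry
    NaN fit values and ``fitted=False``.
    """
    use = _usable_low(session.df)
    use = use[_is_predetermined(use["direction_deg"].to_numpy())]
    low_all = session.df[session.df["condition"].isin(["low_2_1", "low_4_1"])]
    low_all = low_all[low_all["direction_deg"].notna()]
    low_all = low_all[_is_predetermined(low_all["direction_deg"].to_numpy())]

    rows = []
    for mag in DIRECTION_MAGNITUDES:
        sel = use[np.isclose(np.abs(use["direction_deg"]), mag)]
        err = wrap_deg(sel["estimate_deg"].to_numpy()
                       - sel["direction_deg"].to_numpy())
        sign = np.where(sel["direction_deg"].to_numpy() < 0, -1.0, 1.0)
        folded = wrap_deg(err * sign)
        if mag == 0:
            folded = np.concatenate([folded, wrap_deg(-folded)])
        all_mag = low_all[np.isclose(np.abs(low_all["direction_deg"]), mag)]
        det = float(all_mag["detected"].mean()) if len(all_mag) else np.nan
        rt = float(sel["rt_s"].mean()) if len(sel) else np.nan
        row = {"magnitude": mag, "n_est": int(len(sel)), "mean_rt_s": rt,
               "detection_frac": det}
        if len(sel) >= MIN_STRATUM_TRIALS:
            fit = fit_vm_mixture(folded)
            # toward-mode sign: displacement from 16 toward 32 is positive
            # in folded coordinates, from 48/64 toward 32 negative; at 32
            # itself (and 0, where both modes are equidistant) the
            # toward-mode sign is undefined
            toward = fit.mu * (1.0 if mag < 32 else -1.0) \
                if mag not in (0.0, 32.0) else np.nan
            row.update(bias_deg=fit.mu, bias_toward_mode_deg=toward,
                       sigma_deg=fit.sigma, alpha=fit.alpha, fitted=True)
        else:
            row.update(bias_deg=np.nan, bias_toward_mode_deg=np.nan,
                       sigma_deg=np.nan, alpha=np.nan, fitted=False)
        rows.append(row)
    return pd.DataFrame(rows)


def p_ratio(no_stim_estimates, n_bins: int = 11) -> PRatioResult:
    """Hallucination probability ratio over no-stimulus estimates.

    The response range is treated as ``n_bins`` bins of 32 deg centred on
    the predetermined direction lattice; the two bins centred on the prior
    modes (+/-32 deg) are the targets, and an estimate counts as a hit
    when its circular distance to the nearest mode is at most half a bin
    width (estimates in the residual sliver opposite the reference fall in
    the nearest non-target bin). The ratio is the average per-target-bin
    hit probability times ``n_bins``, so responding uniformly across bins
    gives exactly 1 and concentrating all mass on the target bins gives
    ``n_bins / 2``.
    """
    est = np.asarray(list(no_stim_estimates), dtype=float)
    est = est[np.isfinite(est)]
    if est.size == 0:
        return PRatioResult(p_ratio=float("nan"), n_hallucinations=0,
                            n_bins=n_bins, defined=False)
    half_bin = 16.0
    d_plus = np.abs(wrap_deg(est - 32.0))
    d_minus = np.abs(wrap_deg(est + 32.0))
    hit = np.minimum(d_plus, d_minus) <= half_bin
    p_per_target = float(hit.mean()) / 2.0
    return PRatioResult(p_ratio=p_per_target * n_bins,
                        n_hallucinations=int(est.size),
                        n_bins=n_bins, defined=True)


def hallucination_estimates(session: SessionData) -> np.ndarray:
    """Estimates from detected zero-contrast trials."""
    df = session.df
    sel = (df["condition"] == "zero") & df["detected"] & df["estimate_deg"].notna()
    return df.loc[sel, "estimate_deg"].to_numpy(dtype=float)


def _attraction_index(df: pd.DataFrame) -> float:
    """Mean signed error toward the nearest prior mode, non-+/-32 trials.

    The 0-deg stratum is excluded (both modes are equidistant, so the sign
    is undefined there).
    """
    use = _usable_low(df)
    use = use[_is_predetermined(use["direction_deg"].to_numpy())]
    d = use["direction_deg"].to_numpy(dtype=float)
    keep = (np.abs(np.abs(d) - 32.0) > 1e-9) & (np.abs(d) > 1e-9)
    if not keep.any():
        return float("nan")
    d = d[keep]
    err = wrap_deg(use["estimate_deg"].to_numpy(dtype=float)[keep] - d)
    mode = 32.0 * np.sign(d)
    toward = np.sign(wrap_deg(mode - d))
    return float(np.mean(err * toward))


def learning_dynamics(session: SessionData, window: int = 110,
                      step: int = 55) -> pd.DataFrame:
    """Windowed behavioural series over trial order.

    For each (overlapping) window of ``window`` trials, report the cheap
    attraction-bias index (mean signed error toward the nearest prior mode
    at non-+/-32 predetermined directions — a mixture fit would be
    unstable at these window sizes), the detection fraction at +/-32 vs.
    the other predetermined directions, and the mean estimation RT at
    +/-32 vs. others. Windows without usable trials yield NaN.
    """
    df = session.df.sort_values("trial_index").reset_index(drop=True)
    n = len(df)
    if window > n:
        raise ValueError(f"window {window} exceeds session length {n}")
    rows = []
    start = 0
    while start < n:
        stop = min(start + window, n)
        win = df.iloc[start:stop]
        low = win[win["condition"].isin(["low_2_1", "low_4_1"])]
        low = low[low["direction_deg"].notna()]
        low = low[_is_predetermined(low["direction_deg"].to_numpy())]
        at32 = np.isclose(np.abs(low["direction_deg"]), 32.0)
        use = low[low["estimate_deg"].notna() & low["detected"]]
        use32 = np.isclose(np.abs(use["direction_deg"]), 32.0)

        def _mean(x):
            return float(np.mean(x)) if len(x) else float("nan")

        rows.append({
            "window_start": int(win["trial_index"].iloc[0]),
            "window_stop": int(win["trial_index"].iloc[-1]) + 1,
            "n_low_trials": int(len(low)),
            "attraction_bias_deg": _attraction_index(win),
            "detection_32": _mean(low.loc[at32, "detected"]),
            "detection_other": _mean(low.loc[~at32, "detected"]),
            "rt_32_s": _mean(use.loc[use32, "rt_s"].dropna()),
            "rt_other_s": _mean(use.loc[~use32, "rt_s"].dropna()),
        })
        if stop == n:
            break
        start += step
    return pd.DataFrame(rows)
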