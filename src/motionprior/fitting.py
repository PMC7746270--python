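"""Maximum-likelihood observer-model fitting and model comparison.

Per session: the motor noise ``sigma_m`` is first estimated from
high-contrast trials (a von-Mises-plus-uniform mixture fit, whose uniform
component absorbs lapses) and then held fixed; the remaining observer
parameters are fitted by maximizing the summed log response density at the
observed estimates over usable low-contrast trials (estimate made and
stimulus reported seen; the two staircases pooled). Optimization is
bounded L-BFGS-B from a fixed Latin-square start grid, so fits are
deterministic given data and settings.

Model comparison offers the two standard routes: fixed effects (BIC summed
across subjects) and random effects (protected exceedance probability from
a variational Dirichlet model over per-subject model frequencies, with the
Bayes omnibus risk protecting against the chance that all models are
equally frequent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import spearmanr

from .behavior import fit_vm_mixture, _usable_low
from .models import (
    ADD_VARIANTS,
    BAYES_VARIANTS,
    AddParams,
    BayesParams,
    _percept_map,
    free_parameter_count,
    grid_angles,
    prior_density,
    vm_density,
    wrap_deg,
)
from .simulate import DetectionConfig, SessionData, TimingConfig, simulate_session
from .task import TaskConfig, generate_schedule

__all__ = [
    "FitSettings",
    "ModelFitResult",
    "PxpResult",
    "estimate_motor_noise",
    "fit_model",
    "fixed_effects_compare",
    "protected_exceedance_probability",
    "parameter_recovery",
]

#: box bounds for the fitted parameters, degrees (alpha/weight unitless)
DEFAULT_BOUNDS = {
    "theta_p": (5.0, 80.0),
    "sigma_p": (2.0, 120.0),
    "sigma_s": (2.0, 80.0),
    "alpha_p": (0.0, 0.5),
    "w_prior": (0.0, 1.0),
}


@dataclass(frozen=True)
class FitSettings:
    """Optimizer settings. ``n_starts`` Latin-square start points are
    screened by their raw NLL and the best ``polish_top`` of them (all,
    when None) are polished by bounded L-BFGS-B; ``seed`` fixes the
    start-grid permutations (and only those — the likelihood itself is
    deterministic)."""

    n_starts: int = 12
    polish_top: int | None = None
    grid_step: float = 1.0
    maxiter: int = 200
    seed: int = 0
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))


@dataclass(frozen=True)
class ModelFitResult:
    variant: str
    params: BayesParams | AddParams
    sigma_m: float
    nll: float
    n_trials: int
    bic: float
    converged: bool
    best_start: int


@dataclass(frozen=True)
class PxpResult:
    """Random-effects model comparison output.

    ``alpha`` is the Dirichlet posterior over model frequencies,
    ``exceedance`` the unprotected exceedance probabilities, ``bor`` the
    Bayes omnibus risk (posterior probability that model frequencies are
    exchangeable), and ``pxp = (1 - bor) * exceedance + bor / K``.
    """

    alpha: np.ndarray
    model_frequencies: np.ndarray
    exceedance: np.ndarray
    pxp: np.ndarray
    bor: float


def estimate_motor_noise(session: SessionData, min_trials: int = 20) -> float:
    """Motor-noise width (degrees) from high-contrast estimation errors.

    The sigma of a von-Mises-plus-uniform mixture fit; the uniform
    component keeps occasional lapses from inflating the estimate.
    """
    df = session.df
    high = df[(df["condition"] == "high") & df["detected"]
              & df["estimate_deg"].notna() & df["direction_deg"].notna()]
    if len(high) < min_trials:
        raise ValueError(
            f"need >= {min_trials} usable high-contrast trials, got {len(high)}")
    err = wrap_deg(high["estimate_deg"].to_numpy() - high["direction_deg"].to_numpy())
    return fit_vm_mixture(err).sigma


# ---------------------------------------------------------------------------
# likelihood machinery


def _param_names(variant: str) -> list[str]:
    if variant in ("BAYES_P", "BAYES"):
        return ["theta_p", "sigma_p", "sigma_s", "alpha_p"]
    if variant == "BAYES_varmin":
        return ["theta_p", "sigma_p", "sigma_s", "sigma_s", "alpha_p"]
    if variant == "BAYES_var":
        return ["theta_p", "sigma_p"] + ["sigma_s"] * 5 + ["alpha_p"]
    if variant in ADD_VARIANTS:
        return ["theta_p", "sigma_p", "sigma_s", "alpha_p", "w_prior"]
    raise ValueError(f"unknown variant {variant!r}")


def _vector_to_params(x: np.ndarray, variant: str, sigma_m: float):
    x = np.asarray(x, dtype=float)
    if variant in ("BAYES_P", "BAYES"):
        return BayesParams(theta_p=x[0], sigma_p=x[1], sigma_s=float(x[2]),
                           alpha_p=x[3], sigma_m=sigma_m)
    if variant == "BAYES_varmin":
        return BayesParams(theta_p=x[0], sigma_p=x[1],
                           sigma_s=(float(x[2]), float(x[3])),
                           alpha_p=x[4], sigma_m=sigma_m)
    if variant == "BAYES_var":
        return BayesParams(theta_p=x[0], sigma_p=x[1],
                           sigma_s=tuple(float(v) for v in x[2:7]),
                           alpha_p=x[7], sigma_m=sigma_m)
    return AddParams(theta_p=x[0], sigma_p=x[1], sigma_s=float(x[2]),
                     alpha_p=x[3], sigma_m=sigma_m, w_prior=x[4])


class _SessionLikelihood:
    """Precomputed quantities for fast repeated NLL evaluation."""

    def __init__(self, session: SessionData, variant: str, sigma_m: float,
                 grid_step: float = 1.0):
        use = _usable_low(session.df)
        if use.empty:
            raise ValueError("no usable low-contrast estimation trials")
        self.variant = variant
        self.sigma_m = float(sigma_m)
        self.est = use["estimate_deg"].to_numpy(dtype=float)
        self.dirs = use["direction_deg"].to_numpy(dtype=float)
        self.n = self.est.size
        self.grid = grid_angles(grid_step)
        self.step = grid_step
        # motor kernel on the grid and at the observed estimates: sigma_m
        # is fixed, so both are constants of the session
        offs = grid_step * np.arange(self.grid.size)
        self._motor_fft = np.fft.fft(vm_density(offs, 0.0, self.sigma_m))
        self._motor_at_est = vm_density(
            self.est[:, None] - self.grid[None, :], 0.0, self.sigma_m)
        self.unique_dirs, self._dir_idx = np.unique(self.dirs,
                                                    return_inverse=True)
        # single-entry memos: L-BFGS-B gradient steps perturb one
        # parameter at a time, so most stages can be reused across evals
        self._lapse_memo: tuple | None = None
        self._main_memo: tuple | None = None

    def _lapse_at_est(self, params) -> np.ndarray:
        """Lapse density at the observed estimates (uniform or prior
        convolved with motor noise)."""
        prior_based = not (self.variant == "BAYES"
                           or self.variant.endswith("_u"))
        if not prior_based:
            return np.full(self.n, 1.0 / 360.0)
        key = (params.theta_p, params.sigma_p)
        if self._lapse_memo is None or self._lapse_memo[0] != key:
            prior = prior_density(self.grid, params.theta_p, params.sigma_p)
            self._lapse_memo = (key, self._motor_at_est @ (prior * self.step))
        return self._lapse_memo[1]

    def _weight_matrix(self, sigma_s: float, dir_sel: np.ndarray) -> np.ndarray:
        """Sensed-direction weights, one row per selected unique direction."""
        w = vm_density(self.grid[None, :] - self.unique_dirs[dir_sel, None],
                       0.0, sigma_s) * self.step
        return w / w.sum(axis=1, keepdims=True)

    def nll(self, x: np.ndarray) -> float:
        try:
            params = _vector_to_params(x, self.variant, self.sigma_m)
        except ValueError:
            return 1e12
        try:
            if self.variant in BAYES_VARIANTS:
                dens = self._density_bayes(params)
            else:
                dens = self._density_add(params)
        except FloatingPointError:
            return 1e12
        dens = (1.0 - params.alpha_p) * dens \
            + params.alpha_p * self._lapse_at_est(params)
        return float(-np.sum(np.log(np.maximum(dens, 1e-300))))

    def _density_bayes(self, params: BayesParams) -> np.ndarray:
        key = (params.theta_p, params.sigma_p, params.sigma_s)
        if self._main_memo is not None and self._main_memo[0] == key:
            return self._main_memo[1]
        sigmas = np.array([params.sigma_s_for(d, self.variant)
                           for d in self.unique_dirs])
        dens = np.empty(self.n)
        for sig in np.unique(sigmas):
            mu = _percept_map(sig, params, self.grid)
            motor_mu = vm_density(self.est[:, None] - mu[None, :],
                                  0.0, params.sigma_m)
            dir_sel = np.isclose(sigmas, sig)
            w = self._weight_matrix(sig, dir_sel)
            # map each trial to its direction's weight row
            row_of = np.full(self.unique_dirs.size, -1)
            row_of[dir_sel] = np.arange(int(dir_sel.sum()))
            rows = dir_sel[self._dir_idx]
            dens[rows] = np.einsum(
                "ij,ij->i", motor_mu[rows], w[row_of[self._dir_idx[rows]]])
        self._main_memo = (key, dens)
        return dens

    def _density_add(self, params: AddParams) -> np.ndarray:
        w = self._weight_matrix(params.sigma_s, np.ones_like(self.unique_dirs,
                                                             dtype=bool))
        dens = np.einsum("ij,ij->i", self._motor_at_est, w[self._dir_idx])
        if "sample" in self.variant:
            prior = prior_density(self.grid, params.theta_p, params.sigma_p)
            prior_route = self._motor_at_est @ (prior * self.step)
        else:
            prior_route = 0.5 * (
                vm_density(self.est, params.theta_p, params.sigma_m)
                + vm_density(self.est, -params.theta_p, params.sigma_m))
        return params.w_prior * prior_route + (1.0 - params.w_prior) * dens


def _latin_starts(names: Sequence[str], bounds: Mapping, n_starts: int,
                  seed: int) -> np.ndarray:
    """Fixed Latin-square start grid: each dimension visits the midpoints
    of ``n_starts`` equal slices in a seeded permutation."""
    rng = np.random.default_rng(seed)
    levels = (np.arange(n_starts) + 0.5) / n_starts
    cols = []
    for name in names:
        lo, hi = bounds[name]
        cols.append(lo + rng.permutation(levels) * (hi - lo))
    return np.column_stack(cols)


def fit_model(session: SessionData, variant: str, sigma_m: float,
              settings: FitSettings | None = None) -> ModelFitResult:
    """Fit one observer-model variant to one session by MLE.

    Uses low-contrast trials with an estimate and a "seen" report, both
    staircases pooled; the density of the observed estimate given the
    presented direction is evaluated exactly (no grid interpolation of the
    response distribution). Raises if every optimizer start fails.
    """
    settings = settings or FitSettings()
    like = _SessionLikelihood(session, variant, sigma_m, settings.grid_step)
    names = _param_names(variant)
    starts = _latin_starts(names, settings.bounds, settings.n_starts,
                           settings.seed)
    bounds = [settings.bounds[n] for n in names]
    if settings.polish_top is not None:
        screen = np.array([like.nll(x0) for x0 in starts])
        keep = np.argsort(screen)[:settings.polish_top]
    else:
        keep = np.arange(len(starts))
    best, best_i = None, -1
    failures = []
    for i in keep:
        x0 = starts[i]
        res = minimize(like.nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": settings.maxiter})
        if not np.isfinite(res.fun):
            failures.append((i, res.message))
            continue
        if best is None or res.fun < best.fun:
            best, best_i = res, i
    if best is None:
        raise RuntimeError(f"all {len(starts)} starts failed: {failures}")
    params = _vector_to_params(best.x, variant, sigma_m)
    k = free_parameter_count(variant)
    bic = k * np.log(like.n) + 2.0 * best.fun
    return ModelFitResult(variant=variant, params=params, sigma_m=sigma_m,
                          nll=float(best.fun), n_trials=like.n,
                          bic=float(bic), converged=bool(best.success),
                          best_start=best_i)


# ---------------------------------------------------------------------------
# model comparison


def fixed_effects_compare(
        fits: Mapping[str, Mapping[str, ModelFitResult]]) -> pd.DataFrame:
    """Fixed-effects comparison: BIC summed across subjects per variant.

    ``fits`` maps subject -> variant -> fit. Every subject must be fitted
    under every variant. Returns one row per variant with ``total_bic``
    and ``delta_bic`` relative to the best (minimum) variant.
    """
    subjects = list(fits)
    if not subjects:
        raise ValueError("no fits supplied")
    variants = sorted(fits[subjects[0]])
    for s in subjects:
        if sorted(fits[s]) != variants:
            raise ValueError(f"subject {s} is missing some variants")
    total = {v: sum(fits[s][v].bic for s in subjects) for v in variants}
    best = min(total.values())
    out = pd.DataFrame({
        "variant": variants,
        "total_bic": [total[v] for v in variants],
        "delta_bic": [total[v] - best for v in variants],
        "n_subjects": len(subjects),
    })
    return out.sort_values("total_bic").reset_index(drop=True)


def _dirichlet_vb(lme: np.ndarray, alpha0: float = 1.0,
                  tol: float = 1e-8, max_iter: int = 10_000):
    """Variational posterior over model frequencies given log evidences."""
    n, k = lme.shape
    alpha = np.full(k, alpha0 + n / k)
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def _free_energy_h1(lme: np.ndarray, alpha: np.ndarray, u: np.ndarray,
                    alpha0: float = 1.0) -> float:
    n, k = lme.shape
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    elj = (gammaln(k * alpha0) - k * gammaln(alpha0)
           + float(((alpha0 - 1.0) * e_log_r).sum())
           + float((u * (lme + e_log_r)).sum()))
    ent_r = (gammaln(alpha).sum() - gammaln(alpha.sum())
             - float(((alpha - 1.0) * e_log_r).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_u = -float(np.nansum(u * np.log(u)))
    return elj + ent_r + ent_u


def _free_energy_h0(lme: np.ndarray) -> float:
    n, k = lme.shape
    return float(logsumexp(lme - np.log(k), axis=1).sum())


def protected_exceedance_probability(bic_matrix, *, n_samples: int = 100_000,
                                     seed: int = 0) -> PxpResult:
    """Random-effects model comparison from a subjects-by-models BIC table.

    Log model evidence is approximated as ``-BIC / 2``. A variational
    Dirichlet scheme yields the posterior over population model
    frequencies; exceedance probabilities come from Monte Carlo samples of
    that Dirichlet (seeded); the Bayes omnibus risk compares the
    frequency model against the null of exchangeable frequencies and
    shrinks the exceedance probabilities toward 1/K accordingly.
    """
    bic = np.asarray(bic_matrix, dtype=float)
    if bic.ndim != 2 or bic.shape[0] < 2 or bic.shape[1] < 2:
        raise ValueError("need a (>=2 subjects) x (>=2 models) BIC matrix")
    if not np.all(np.isfinite(bic)):
        raise ValueError("BIC matrix contains non-finite entries")
    lme = -bic / 2.0
    lme = lme - lme.max(axis=1, keepdims=True)  # per-subject shift, no effect
    n, k = lme.shape
    alpha, u = _dirichlet_vb(lme)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=k) / n_samples
    f1 = _free_energy_h1(lme, alpha, u)
    f0 = _free_energy_h0(lme)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / k
    return PxpResult(alpha=alpha, model_frequencies=alpha / alpha.sum(),
                     exceedance=ep, pxp=pxp, bor=bor)


# ---------------------------------------------------------------------------
# recovery harnesses


def parameter_recovery(true_params_list: Sequence[BayesParams],
                       config: TaskConfig | None = None,
                       seed: int = 0,
                       *,
                       variant: str = "BAYES_P",
                       det: DetectionConfig | None = None,
                       timing: TimingConfig | None = None,
                       settings: FitSettings | None = None) -> dict:
    """Simulate -> fit -> tabulate for a list of ground-truth observers.

    Each observer gets its own schedule and session seed derived from
    ``seed``. Per-observer fit failures are recorded in the table (NaN
    row), not raised. Returns the true-vs-recovered table, per-parameter
    Spearman rank correlations and median absolute errors.
    """
    config = config or TaskConfig()
    rows = []
    for i, true in enumerate(true_params_list):
        sched = generate_schedule(config, seed=seed + 1000 * i)
        sess = simulate_session(sched, true, det, seed=seed + 1000 * i + 1,
                                variant=variant, timing=timing,
                                observer_id=f"sim{i}")
        row = {"observer": f"sim{i}",
               "true_theta_p": true.theta_p, "true_sigma_p": true.sigma_p,
               "true_sigma_s": true.sigma_s, "true_alpha_p": true.alpha_p,
               "true_sigma_m": true.sigma_m}
        try:
            sm = estimate_motor_noise(sess)
            fit = fit_model(sess, variant, sm, settings)
            row.update(fit_theta_p=fit.params.theta_p,
                       fit_sigma_p=fit.params.sigma_p,
                       fit_sigma_s=fit.params.sigma_s,
                       fit_alpha_p=fit.params.alpha_p,
                       fit_sigma_m=sm, nll=fit.nll, error="")
        except (ValueError, RuntimeError) as exc:
            row.update(fit_theta_p=np.nan, fit_sigma_p=np.nan,
                       fit_sigma_s=np.nan, fit_alpha_p=np.nan,
                       fit_sigma_m=np.nan, nll=np.nan, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    stats = {}
    for p in ("theta_p", "sigma_p", "sigma_s", "alpha_p"):
        t = pd.to_numeric(table[f"true_{p}"], errors="coerce")
        f = pd.to_numeric(table[f"fit_{p}"], errors="coerce")
        ok = t.notna() & f.notna()
        if ok.sum() >= 3 and t[ok].nunique() > 1:
            rho = float(spearmanr(t[ok], f[ok]).statistic)
        else:
            rho = float("nan")
        stats[p] = {"spearman_rho": rho,
                    "median_abs_error": float((f[ok] - t[ok]).abs().median())}
    return {"table": table, "stats": stats}
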