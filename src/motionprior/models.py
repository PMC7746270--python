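"""Observer models for motion-direction estimation under a learned bimodal prior.

The generative story, per trial: the presented direction ``theta_act`` is
corrupted by sensory noise into a sensed direction ``theta_s`` (von Mises,
width ``sigma_s``); the observer combines a von Mises likelihood centred on
``theta_s`` with an acquired bimodal prior (two von Mises modes at
``+/-theta_p``, width ``sigma_p``); the percept ``theta_perc`` is the
circular mean of the posterior; with probability ``alpha_p`` the percept is
instead a lapse (drawn from the prior, or uniform, depending on variant);
the reported estimate ``theta_est`` adds motor noise (von Mises, width
``sigma_m``) around the percept.

All angles are degrees. A von Mises "width" ``sigma`` (degrees) maps to the
concentration ``kappa = 1 / sigma_rad**2`` with ``sigma_rad`` in radians —
the usual Gaussian-approximation convention. Densities are per degree, so a
density summed over a uniform grid times the grid step equals 1.

Model variants
--------------
``BAYES_P``
    scalar ``sigma_s``; lapses drawn from the prior (4 free parameters).
``BAYES``
    scalar ``sigma_s``; uniform lapses (4 free parameters).
``BAYES_varmin``
    ``sigma_s`` differs between the prior modes (+/-32 deg) and all other
    directions; prior-based lapses (5 free parameters).
``BAYES_var``
    one ``sigma_s`` per absolute direction magnitude {0, 16, 32, 48, 64};
    prior-based lapses (8 free parameters).

The non-Bayesian ``ADD`` class mixes a prior-only and a likelihood-only
response route instead of multiplying the two densities. The four concrete
ADD forms implemented here (prior-sample vs. prior-mode responding, crossed
with uniform vs. prior-based lapses) are canonical reconstructions of that
strategy class, not transcriptions of a published table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

__all__ = [
    "BAYES_VARIANTS",
    "ADD_VARIANTS",
    "DIRECTION_MAGNITUDES",
    "BayesParams",
    "AddParams",
    "ResponseGrid",
    "wrap_deg",
    "circ_mean_deg",
    "kappa_from_sigma",
    "vm_density",
    "prior_density",
    "posterior_mean",
    "response_distribution",
    "add_response_distribution",
    "response_density_at",
]

BAYES_VARIANTS = ("BAYES_P", "BAYES", "BAYES_varmin", "BAYES_var")
ADD_VARIANTS = ("ADD_sample_u", "ADD_sample_p", "ADD_mode_u", "ADD_mode_p")

#: absolute predetermined direction magnitudes, degrees
DIRECTION_MAGNITUDES = (0.0, 16.0, 32.0, 48.0, 64.0)

#: default angular grid step in degrees
GRID_STEP = 1.0


def wrap_deg(angle):
    """Wrap angles (degrees) into ``[-180, 180)``."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def grid_angles(step: float = GRID_STEP) -> np.ndarray:
    """Uniform angular grid over ``[-180, 180)`` with the given step."""
    n = int(round(360.0 / step))
    if abs(n * step - 360.0) > 1e-9:
        raise ValueError("grid step must divide 360 degrees")
    return -180.0 + step * np.arange(n)


def circ_mean_deg(angles, weights=None) -> float:
    """Circular mean (argument of the resultant vector), in degrees.

    Raises
    ------
    FloatingPointError
        If the resultant vector has (numerically) zero length, in which
        case the circular mean is undefined.
    """
    rad = np.deg2rad(np.asarray(angles, dtype=float))
    z = np.exp(1j * rad)
    if weights is not None:
        z = np.asarray(weights, dtype=float) * z
    r = z.sum()
    if not np.isfinite(r) or abs(r) < 1e-300:
        raise FloatingPointError("circular mean undefined: zero resultant")
    return float(np.rad2deg(np.angle(r)))


def kappa_from_sigma(sigma_deg: float) -> float:
    """Von Mises concentration for a width ``sigma`` in degrees."""
    if sigma_deg <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_deg}")
    return 1.0 / np.deg2rad(sigma_deg) ** 2


def vm_density(angle, mu, sigma):
    """Von Mises density ``V(mu, sigma)`` evaluated at ``angle``, per degree.

    Uses the exponentially scaled Bessel function so large concentrations
    (small widths) do not overflow.
    """
    kappa = kappa_from_sigma(sigma)
    delta = np.deg2rad(np.asarray(angle, dtype=float) - mu)
    pdf_rad = np.exp(kappa * (np.cos(delta) - 1.0)) / (2.0 * np.pi * i0e(kappa))
    return pdf_rad * (np.pi / 180.0)


def prior_density(theta, theta_p, sigma_p):
    """Bimodal acquired prior: equal-weight von Mises modes at ``+/-theta_p``."""
    return 0.5 * (
        vm_density(theta, theta_p, sigma_p) + vm_density(theta, -theta_p, sigma_p)
    )


def _uniform_density(theta):
    return np.full_like(np.asarray(theta, dtype=float), 1.0 / 360.0)


@dataclass(frozen=True)
class BayesParams:
    """Parameters of the Bayesian observer.

    ``sigma_s`` is a scalar for BAYES/BAYES_P, a pair ``(at +/-32, other)``
    for BAYES_varmin, and five values (one per direction magnitude
    0/16/32/48/64) for BAYES_var. ``sigma_m`` is the motor noise, fixed
    during fitting.
    """

    theta_p: float
    sigma_p: float
    sigma_s: float | tuple[float, ...]
    alpha_p: float
    sigma_m: float

    def __post_init__(self):
        ss = self.sigma_s if isinstance(self.sigma_s, tuple) else (self.sigma_s,)
        if any(s <= 0 for s in (self.sigma_p, self.sigma_m, *ss)):
            raise ValueError("all widths must be positive")
        if not 0.0 <= self.alpha_p <= 1.0:
            raise ValueError("alpha_p must lie in [0, 1]")
        if not 0.0 < self.theta_p <= 90.0:
            raise ValueError("theta_p must lie in (0, 90] degrees")

    def sigma_s_for(self, theta_act: float, variant: str) -> float:
        """Sensory width applying to a presented direction, per variant.

        Directions off the predetermined set (random-direction trials) use
        the sigma of the nearest magnitude.
        """
        ss = self.sigma_s
        if variant in ("BAYES_P", "BAYES"):
            if isinstance(ss, tuple):
                if len(ss) != 1:
                    raise ValueError(f"{variant} expects a scalar sigma_s")
                return ss[0]
            return float(ss)
        mag = abs(wrap_deg(theta_act))
        if variant == "BAYES_varmin":
            if not (isinstance(ss, tuple) and len(ss) == 2):
                raise ValueError("BAYES_varmin expects sigma_s = (at_32, other)")
            return ss[0] if abs(mag - 32.0) < 8.0 else ss[1]
        if variant == "BAYES_var":
            if not (isinstance(ss, tuple) and len(ss) == 5):
                raise ValueError("BAYES_var expects 5 sigma_s values")
            idx = int(np.argmin([abs(mag - m) for m in DIRECTION_MAGNITUDES]))
            return ss[idx]
        raise ValueError(f"unknown Bayesian variant {variant!r}")


@dataclass(frozen=True)
class AddParams:
    """Parameters of the ADD (prior-or-likelihood) observer.

    ``w_prior`` is the per-trial probability of responding from the prior
    route rather than the likelihood route.
    """

    theta_p: float
    sigma_p: float
    sigma_s: float
    alpha_p: float
    sigma_m: float
    w_prior: float

    def __post_init__(self):
        if any(s <= 0 for s in (self.sigma_p, self.sigma_m, self.sigma_s)):
            raise ValueError("all widths must be positive")
        if not 0.0 <= self.alpha_p <= 1.0:
            raise ValueError("alpha_p must lie in [0, 1]")
        if not 0.0 <= self.w_prior <= 1.0:
            raise ValueError("w_prior must lie in [0, 1]")
        if not 0.0 < self.theta_p <= 90.0:
            raise ValueError("theta_p must lie in (0, 90] degrees")


@dataclass(frozen=True)
class ResponseGrid:
    """A response-probability density tabulated on a uniform angular grid."""

    angles: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        if self.angles.shape != self.density.shape:
            raise ValueError("angles and density must have equal shape")
        total = float(self.density.sum() * self.step)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"density does not normalize: mass {total}")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.angles[1] - self.angles[0])

    def circular_mean(self) -> float:
        return circ_mean_deg(self.angles, self.density * self.step)

    def density_at(self, angle) -> np.ndarray:
        """Nearest-grid-point lookup of the density."""
        idx = np.round((wrap_deg(angle) - self.angles[0]) / self.step).astype(int)
        idx %= len(self.angles)
        return self.density[idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"angle_deg": self.angles, "density": self.density})


def posterior_mean(theta_s, params: BayesParams, *, variant: str = "BAYES_P",
                   step: float = GRID_STEP):
    """Percept for a sensed direction: circular mean of prior x likelihood.

    Accepts a scalar or an array of sensed directions. The posterior is
    formed on a uniform grid and its circular mean taken; a posterior whose
    resultant vanishes (possible only for pathological parameter sets)
    raises ``FloatingPointError``.
    """
    theta_s_arr = np.atleast_1d(np.asarray(theta_s, dtype=float))
    grid = grid_angles(step)
    prior = prior_density(grid, params.theta_p, params.sigma_p)
    zg = np.exp(1j * np.deg2rad(grid))
    out = np.empty(theta_s_arr.shape, dtype=float)
    if variant in ("BAYES_P", "BAYES"):
        sig = params.sigma_s_for(0.0, variant)
        like = vm_density(grid[None, :] - theta_s_arr[:, None], 0.0, sig)
        res = (like * prior[None, :]) @ zg
        bad = np.abs(res) < 1e-300
        if np.any(bad):
            raise FloatingPointError("degenerate posterior: zero resultant")
        out[:] = np.rad2deg(np.angle(res))
    else:
        for i, ts in np.ndenumerate(theta_s_arr):
            sig = params.sigma_s_for(float(ts), variant)
            post = vm_density(grid, float(ts), sig) * prior
            out[i] = circ_mean_deg(grid, post)
    if np.isscalar(theta_s) or np.asarray(theta_s).ndim == 0:
        return float(out.flat[0])
    return out


def _percept_map(sigma_s: float, params: BayesParams, grid: np.ndarray) -> np.ndarray:
    """Percept mu(theta_s) for every theta_s on the grid (one sigma_s).

    The posterior resultant for all sensed directions at once is a
    circular cross-correlation of the von Mises likelihood kernel with
    ``prior * exp(i * theta)``, evaluated by FFT; identical (to rounding)
    to forming each posterior explicitly.
    """
    step = float(grid[1] - grid[0])
    offsets = step * np.arange(grid.size)
    kern = vm_density(offsets, 0.0, sigma_s)
    prior = prior_density(grid, params.theta_p, params.sigma_p)
    zg = np.exp(1j * np.deg2rad(grid))
    res = np.fft.ifft(np.conj(np.fft.fft(kern)) * np.fft.fft(zg * prior))
    # FFT round-off floods resultants many orders below the peak (sensed
    # directions far from both prior modes); recompute those in log space
    mag = np.abs(res)
    bad = mag < mag.max() * 1e-10
    if np.any(bad):
        kappa_s = kappa_from_sigma(sigma_s)
        kappa_p = kappa_from_sigma(params.sigma_p)
        lp_prior = np.logaddexp(
            kappa_p * (np.cos(np.deg2rad(grid - params.theta_p)) - 1.0),
            kappa_p * (np.cos(np.deg2rad(grid + params.theta_p)) - 1.0))
        for j in np.flatnonzero(bad):
            lp = lp_prior + kappa_s * (np.cos(np.deg2rad(grid - grid[j])) - 1.0)
            w = np.exp(lp - lp.max())
            res[j] = w @ zg
    if np.any(np.abs(res) < 1e-300):
        raise FloatingPointError("degenerate posterior: zero resultant")
    return np.rad2deg(np.angle(res))


def _lapse_density(eval_at: np.ndarray, params, *, prior_based: bool,
                   step: float) -> np.ndarray:
    """Lapse response density: prior convolved with motor noise, or uniform."""
    if not prior_based:
        return _uniform_density(eval_at)
    grid = grid_angles(step)
    prior = prior_density(grid, params.theta_p, params.sigma_p)
    motor = vm_density(eval_at[:, None] - grid[None, :], 0.0, params.sigma_m)
    return motor @ (prior * step)


def _prior_based_lapse(variant: str) -> bool:
    return variant != "BAYES"


def response_density_at(theta_act: float, eval_at, params: BayesParams,
                        variant: str = "BAYES_P", *,
                        step: float = GRID_STEP) -> np.ndarray:
    """Response density ``p(theta_est | theta_act)`` at arbitrary angles.

    Marginalizes the sensed direction over the grid:
    ``sum_j p(theta_s_j | theta_act) (1 - alpha_p) V(mu(theta_s_j), sigma_m)``
    plus the lapse term. Exact at the requested angles (no interpolation).
    """
    if variant not in BAYES_VARIANTS:
        raise ValueError(f"unknown Bayesian variant {variant!r}")
    eval_arr = np.atleast_1d(np.asarray(eval_at, dtype=float))
    grid = grid_angles(step)
    sigma_s = params.sigma_s_for(theta_act, variant)
    mu = _percept_map(sigma_s, params, grid)
    w = vm_density(grid, theta_act, sigma_s) * step
    w /= w.sum()
    motor = vm_density(eval_arr[:, None] - mu[None, :], 0.0, params.sigma_m)
    main = motor @ w
    lapse = _lapse_density(eval_arr, params,
                           prior_based=_prior_based_lapse(variant), step=step)
    out = (1.0 - params.alpha_p) * main + params.alpha_p * lapse
    if np.isscalar(eval_at) or np.asarray(eval_at).ndim == 0:
        return float(out[0])
    return out


def response_distribution(theta_act: float, params: BayesParams,
                          variant: str = "BAYES_P", *,
                          step: float = GRID_STEP) -> ResponseGrid:
    """Full response distribution of a Bayesian observer on the grid."""
    grid = grid_angles(step)
    dens = response_density_at(theta_act, grid, params, variant, step=step)
    dens = np.maximum(dens, 0.0)
    dens /= dens.sum() * step
    return ResponseGrid(angles=grid, density=dens)


def add_response_density_at(theta_act: float, eval_at, params: AddParams,
                            variant: str = "ADD_sample_p", *,
                            step: float = GRID_STEP) -> np.ndarray:
    """Response density for the ADD (prior-or-likelihood) observer.

    The likelihood route reports the sensed direction plus motor noise; the
    prior route either samples the prior (``sample`` forms) or reports one
    of the two prior modes at random (``mode`` forms), plus motor noise.
    Lapses are uniform (``_u`` forms) or prior-based (``_p`` forms).
    """
    if variant not in ADD_VARIANTS:
        raise ValueError(f"unknown ADD variant {variant!r}")
    eval_arr = np.atleast_1d(np.asarray(eval_at, dtype=float))
    grid = grid_angles(step)

    w = vm_density(grid, theta_act, params.sigma_s) * step
    w /= w.sum()
    motor_like = vm_density(eval_arr[:, None] - grid[None, :], 0.0, params.sigma_m)
    likelihood_route = motor_like @ w

    if "sample" in variant:
        prior = prior_density(grid, params.theta_p, params.sigma_p)
        prior_route = motor_like @ (prior * step)
    else:
        prior_route = 0.5 * (
            vm_density(eval_arr, params.theta_p, params.sigma_m)
            + vm_density(eval_arr, -params.theta_p, params.sigma_m)
        )

    mix = params.w_prior * prior_route + (1.0 - params.w_prior) * likelihood_route
    lapse = _lapse_density(eval_arr, params,
                           prior_based=variant.endswith("_p"), step=step)
    out = (1.0 - params.alpha_p) * mix + params.alpha_p * lapse
    if np.isscalar(eval_at) or np.asarray(eval_at).ndim == 0:
        return float(out[0])
    return out


def add_response_distribution(theta_act: float, params: AddParams,
                              variant: str = "ADD_sample_p", *,
                              step: float = GRID_STEP) -> ResponseGrid:
    """Full ADD-observer response distribution on the grid."""
    grid = grid_angles(step)
    dens = add_response_density_at(theta_act, grid, params, variant, step=step)
    dens = np.maximum(dens, 0.0)
    dens /= dens.sum() * step
    return ResponseGrid(angles=grid, density=dens)


def free_parameter_count(variant: str) -> int:
    """Number of free parameters fitted for a model variant."""
    counts = {
        "BAYES_P": 4, "BAYES": 4, "BAYES_varmin": 5, "BAYES_var": 8,
        "ADD_sample_u": 5, "ADD_sample_p": 5, "ADD_mode_u": 5, "ADD_mode_p": 5,
    }
    try:
        return counts[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None


def params_to_record(params, variant: str) -> dict:
    """Flatten a parameter set into a key/value record with a variant tag."""
    rec = {"variant": variant, "theta_p": params.theta_p,
           "sigma_p": params.sigma_p, "alpha_p": params.alpha_p,
           "sigma_m": params.sigma_m}
    ss = params.sigma_s
    if isinstance(ss, tuple):
        for i, s in enumerate(ss):
            rec[f"sigma_s_{i}"] = s
    else:
        rec["sigma_s"] = ss
    if hasattr(params, "w_prior"):
        rec["w_prior"] = params.w_prior
    return rec


def params_from_record(rec: dict):
    """Inverse of :func:`params_to_record`."""
    rec = dict(rec)
    variant = rec.pop("variant")
    keys = sorted(k for k in rec if k.startswith("sigma_s_"))
    if keys:
        sigma_s = tuple(float(rec[k]) for k in keys)
    else:
        sigma_s = float(rec["sigma_s"])
    common = dict(theta_p=float(rec["theta_p"]), sigma_p=float(rec["sigma_p"]),
                  sigma_s=sigma_s, alpha_p=float(rec["alpha_p"]),
                  sigma_m=float(rec["sigma_m"]))
    if variant in ADD_VARIANTS:
        return AddParams(w_prior=float(rec["w_prior"]), **common), variant
    return BayesParams(**common), variant
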