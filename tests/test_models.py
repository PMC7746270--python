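"""Observer-model densities: von Mises machinery, posterior means, and the
full response distributions of the Bayesian and ADD variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize

from motionprior import (
    AddParams,
    BayesParams,
    add_response_distribution,
    posterior_mean,
    prior_density,
    response_distribution,
    vm_density,
)
from motionprior.models import (
    ADD_VARIANTS,
    circ_mean_deg,
    grid_angles,
    kappa_from_sigma,
    params_from_record,
    params_to_record,
    response_density_at,
    wrap_deg,
)

GRID = grid_angles()


def bayes(**kw):
    base = dict(theta_p=32.0, sigma_p=15.0, sigma_s=12.0, alpha_p=0.1,
                sigma_m=8.0)
    base.update(kw)
    return BayesParams(**base)


def mixture_location(rg):
    """Location of a von-Mises-plus-uniform mixture fitted to a response
    grid by weighted maximum likelihood — the model-level analogue of the
    behavioural bias summary."""
    def nll(t):
        mu, s, a = t
        dens = (1 - a) * vm_density(rg.angles, mu, s) + a / 360.0
        return -np.sum(rg.density * np.log(np.maximum(dens, 1e-300)))

    best = None
    for mu0 in (0.0, 32.0):
        for s0 in (10.0, 30.0):
            r = minimize(nll, (mu0, s0, 0.1), method="L-BFGS-B",
                         bounds=[(-180, 180), (0.5, 120), (0, 1)])
            if best is None or r.fun < best.fun:
                best = r
    return best.x[0]


class TestVonMises:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(sigma=st.floats(1.0, 120.0), mu=st.floats(-180.0, 180.0))
    def test_normalizes_and_peaks_at_mu(self, sigma, mu):
        dens = vm_density(GRID, mu, sigma)
        assert np.sum(dens) * 1.0 == pytest.approx(1.0, abs=1e-6)
        assert vm_density(mu, mu, sigma) > vm_density(mu + 180.0, mu, sigma)

    def test_symmetric_about_mu(self):
        assert vm_density(30.0, 10.0, 20.0) == pytest.approx(
            vm_density(-10.0, 10.0, 20.0))

    def test_matches_kappa_quadrature_oracle(self):
        # independent quadrature of the kappa-parameterized density
        sigma = 20.0
        kappa = 1.0 / np.deg2rad(sigma) ** 2

        def pdf_rad(x):
            from scipy.special import i0
            return np.exp(kappa * np.cos(x)) / (2 * np.pi * i0(kappa))

        total, _ = quad(pdf_rad, -np.pi, np.pi)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert vm_density(0.0, 0.0, sigma) == pytest.approx(
            pdf_rad(0.0) * np.pi / 180.0, rel=1e-9)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            vm_density(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            kappa_from_sigma(-1.0)


class TestPrior:
    def test_symmetric_under_negation(self):
        th = np.linspace(-180, 179, 77)
        assert prior_density(th, 32.0, 10.0) == pytest.approx(
            prior_density(-th, 32.0, 10.0))
        assert prior_density(32.0, 32.0, 10.0) == pytest.approx(
            prior_density(-32.0, 32.0, 10.0))

    def test_wide_prior_approaches_uniform(self):
        dens = prior_density(GRID, 32.0, 20_000.0)
        assert dens.max() / dens.min() == pytest.approx(1.0, abs=1e-3)

    def test_modes_at_plus_minus_theta_p(self):
        fine = np.arange(-180.0, 180.0, 0.5)
        dens = prior_density(fine, 32.0, 10.0)
        top2 = fine[np.argsort(dens)[-2:]]
        assert sorted(top2) == [-32.0, 32.0]


class TestPosteriorMean:
    def test_flat_prior_returns_sensed_direction(self):
        p = bayes(sigma_p=5000.0)
        assert posterior_mean(41.0, p) == pytest.approx(41.0, abs=0.1)

    def test_sensed_at_prior_mode_stays_there(self):
        # a sensed direction on the prior mode is nearly unmoved (exactly
        # so only in the unimodal idealization: the opposite mode exerts a
        # small sub-degree pull toward the centre)
        p = bayes(theta_p=32.0)
        assert posterior_mean(32.0, p) == pytest.approx(32.0, abs=0.5)

    def test_matches_fine_grid_brute_force(self):
        # 0.1-degree brute-force circular mean of prior x likelihood
        p = bayes(theta_p=32.0, sigma_p=15.0, sigma_s=20.0, alpha_p=0.0)
        fine = np.arange(-180.0, 180.0, 0.1)
        post = vm_density(fine, 64.0, 20.0) * prior_density(fine, 32.0, 15.0)
        expected = circ_mean_deg(fine, post)
        got = posterior_mean(64.0, p)
        assert got == pytest.approx(expected, abs=0.05)
        assert 32.0 < got < 64.0


def _forward_mc(theta_act, p, variant, n, seed):
    """Monte-Carlo simulation of the generative chain, independent of the
    grid-marginalization code path (fine-grid direct posterior means)."""
    rng = np.random.default_rng(seed)
    fine = np.arange(-180.0, 180.0, 0.1)
    mu_fine = posterior_mean(fine, p)
    lapse = rng.random(n) < p.alpha_p
    ts = np.rad2deg(rng.vonmises(np.deg2rad(theta_act),
                                 kappa_from_sigma(p.sigma_s), size=n))
    idx = np.round((wrap_deg(ts) + 180.0) / 0.1).astype(int) % fine.size
    perc = mu_fine[idx]
    n_lap = int(lapse.sum())
    if variant == "BAYES":
        perc[lapse] = rng.uniform(-180.0, 180.0, size=n_lap)
    else:
        sign = np.where(rng.random(n_lap) < 0.5, 1.0, -1.0)
        perc[lapse] = np.rad2deg(rng.vonmises(
            np.deg2rad(sign * p.theta_p), kappa_from_sigma(p.sigma_p)))
    motor = np.rad2deg(rng.vonmises(0.0, kappa_from_sigma(p.sigma_m), size=n))
    return wrap_deg(perc + motor)


class TestResponseDistribution:
    def test_pure_lapse_is_prior_convolved_with_motor(self):
        p = bayes(alpha_p=1.0)
        a = response_distribution(48.0, p, "BAYES_P")
        b = response_distribution(-16.0, p, "BAYES_P")
        assert a.density == pytest.approx(b.density)  # theta_act irrelevant
        conv = vm_density(GRID[:, None] - GRID[None, :], 0.0, p.sigma_m) @ (
            prior_density(GRID, p.theta_p, p.sigma_p) * 1.0)
        assert a.density == pytest.approx(conv, abs=1e-9)

    def test_noiseless_veridical_limit_concentrates_at_stimulus(self):
        p = bayes(sigma_p=5000.0, sigma_s=0.5, sigma_m=0.5, alpha_p=0.0)
        rg = response_distribution(48.0, p)
        assert rg.circular_mean() == pytest.approx(48.0, abs=0.1)
        # circular variance below grid resolution
        r = np.abs(np.sum(rg.density * np.exp(1j * np.deg2rad(rg.angles))))
        assert np.rad2deg(np.sqrt(-2 * np.log(r))) < 1.5

    @pytest.mark.parametrize("variant,theta_act", [("BAYES_P", 48.0),
                                                   ("BAYES", 16.0)])
    def test_matches_forward_simulation(self, variant, theta_act):
        p = bayes(sigma_s=25.0, sigma_m=10.0)
        est = _forward_mc(theta_act, p, variant, n=200_000, seed=9)
        obs, _ = np.histogram(est, bins=np.linspace(-180, 180, 37))
        obs = obs / est.size
        fine = np.arange(-180.0, 180.0, 0.1)
        pred = response_density_at(theta_act, fine, p, variant)
        pred = pred.reshape(36, -1).sum(axis=1) * 0.1
        se = np.sqrt(pred * (1 - pred) / est.size) + 1e-9
        assert np.max(np.abs(obs - pred) / se) < 4.0

    def test_normalization_over_random_parameter_sweep(self, rng):
        for _ in range(25):
            p = BayesParams(theta_p=float(rng.uniform(5, 80)),
                            sigma_p=float(rng.uniform(3, 100)),
                            sigma_s=float(rng.uniform(3, 70)),
                            alpha_p=float(rng.uniform(0, 1)),
                            sigma_m=float(rng.uniform(2, 30)))
            ta = float(rng.uniform(-180, 180))
            rg = response_distribution(ta, p, "BAYES_P")
            assert np.sum(rg.density) * 1.0 == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("variant", ["BAYES_P", "BAYES"])
    def test_mirror_symmetry(self, variant):
        p = bayes(sigma_s=20.0)
        a = response_distribution(48.0, p, variant).density
        b = response_distribution(-48.0, p, variant).density
        # mirror image: density at angle x equals density at -x
        assert a == pytest.approx(np.roll(b[::-1], 1), abs=1e-12)

    def test_grid_refinement_converges(self):
        p = bayes(sigma_s=20.0)
        m1 = response_distribution(48.0, p, step=1.0).circular_mean()
        m2 = response_distribution(48.0, p, step=0.5).circular_mean()
        assert abs(m1 - m2) < 0.05

    def test_bayes_var_with_equal_sigmas_reproduces_bayes_p(self):
        ss = 18.0
        p_var = bayes(sigma_s=(ss,) * 5)
        p_scalar = bayes(sigma_s=ss)
        for ta in (0.0, 32.0, 64.0, 111.0):
            a = response_distribution(ta, p_var, "BAYES_var").density
            b = response_distribution(ta, p_scalar, "BAYES_P").density
            assert np.max(np.abs(a - b)) < 1e-9

    def test_varmin_uses_mode_specific_sigma(self):
        p = BayesParams(theta_p=32.0, sigma_p=15.0, sigma_s=(5.0, 30.0),
                        alpha_p=0.0, sigma_m=8.0)
        at_mode = response_distribution(32.0, p, "BAYES_varmin")
        off_mode = response_distribution(0.0, p, "BAYES_varmin")
        r = lambda rg: np.abs(np.sum(rg.density
                                     * np.exp(1j * np.deg2rad(rg.angles))))
        assert r(at_mode) > r(off_mode)  # tighter response at the mode

    def test_attraction_toward_nearest_mode_moderate_regime(self):
        # mixture-fit location lies strictly between the stimulus and the
        # 32-degree prior mode for moderate sensory noise
        for sp in (10.0, 15.0, 20.0):
            for ss in (5.0, 10.0, 12.0):
                p = bayes(sigma_p=sp, sigma_s=ss, alpha_p=0.0)
                for ta in (16.0, 48.0, 64.0):
                    mu = mixture_location(response_distribution(ta, p))
                    assert min(ta, 32.0) < mu < max(ta, 32.0), (sp, ss, ta)

    def test_variant_parameter_mismatch_raises(self):
        with pytest.raises(ValueError):
            response_distribution(0.0, bayes(sigma_s=(5.0, 10.0)), "BAYES_P")
        with pytest.raises(ValueError):
            response_distribution(0.0, bayes(), "BAYES_var")
        with pytest.raises(ValueError):
            response_distribution(0.0, bayes(), "NOPE")


class TestAddModels:
    def add(self, **kw):
        base = dict(theta_p=32.0, sigma_p=15.0, sigma_s=12.0, alpha_p=0.1,
                    sigma_m=8.0, w_prior=0.5)
        base.update(kw)
        return AddParams(**base)

    def test_w_zero_is_likelihood_convolved_with_motor(self):
        p = self.add(w_prior=0.0, alpha_p=0.0)
        rg = add_response_distribution(48.0, p, "ADD_sample_u")
        conv = vm_density(GRID[:, None] - GRID[None, :], 0.0, p.sigma_m) @ (
            vm_density(GRID, 48.0, p.sigma_s) * 1.0)
        conv /= conv.sum()
        assert rg.density == pytest.approx(conv, abs=1e-9)

    def test_w_one_prior_modes_dominate(self):
        p = self.add(w_prior=1.0, alpha_p=0.0, sigma_p=10.0)
        rg = add_response_distribution(0.0, p, "ADD_mode_u")
        peaks = rg.angles[np.argsort(rg.density)[-2:]]
        assert sorted(np.round(peaks)) == [-32.0, 32.0]

    @pytest.mark.parametrize("variant", ADD_VARIANTS)
    def test_matches_forward_simulation(self, variant):
        p = self.add()
        n = 100_000
        rng = np.random.default_rng(17)
        lapse = rng.random(n) < p.alpha_p
        prior_route = rng.random(n) < p.w_prior
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        perc = np.rad2deg(rng.vonmises(np.deg2rad(48.0),
                                       kappa_from_sigma(p.sigma_s), size=n))
        prior_draw = np.rad2deg(rng.vonmises(
            np.deg2rad(sign * p.theta_p), kappa_from_sigma(p.sigma_p)))
        if "sample" in variant:
            perc[prior_route] = prior_draw[prior_route]
        else:
            perc[prior_route] = (sign * p.theta_p)[prior_route]
        if variant.endswith("_u"):
            perc[lapse] = rng.uniform(-180, 180, size=int(lapse.sum()))
        else:
            perc[lapse] = prior_draw[lapse]
        est = wrap_deg(perc + np.rad2deg(
            rng.vonmises(0.0, kappa_from_sigma(p.sigma_m), size=n)))
        obs, _ = np.histogram(est, bins=np.linspace(-180, 180, 37))
        obs = obs / n
        from motionprior.models import add_response_density_at

        fine = np.arange(-180.0, 180.0, 0.1)
        pred = add_response_density_at(48.0, fine, p, variant)
        pred = pred.reshape(36, -1).sum(axis=1) * 0.1
        se = np.sqrt(pred * (1 - pred) / n) + 1e-9
        assert np.max(np.abs(obs - pred) / se) < 4.0


class TestParamRecords:
    @pytest.mark.parametrize("params,variant", [
        (BayesParams(theta_p=30, sigma_p=12, sigma_s=20, alpha_p=0.1,
                     sigma_m=7), "BAYES_P"),
        (BayesParams(theta_p=30, sigma_p=12, sigma_s=(5, 6, 7, 8, 9),
                     alpha_p=0.1, sigma_m=7), "BAYES_var"),
        (AddParams(theta_p=30, sigma_p=12, sigma_s=20, alpha_p=0.1,
                   sigma_m=7, w_prior=0.4), "ADD_sample_p"),
    ])
    def test_round_trip(self, params, variant):
        rec = params_to_record(params, variant)
        back, v = params_from_record(rec)
        assert v == variant
        assert back == params

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BayesParams(theta_p=0.0, sigma_p=10, sigma_s=10, alpha_p=0.1,
                        sigma_m=8)
        with pytest.raises(ValueError):
            BayesParams(theta_p=32, sigma_p=-1, sigma_s=10, alpha_p=0.1,
                        sigma_m=8)
        with pytest.raises(ValueError):
            AddParams(theta_p=32, sigma_p=10, sigma_s=10, alpha_p=0.1,
                      sigma_m=8, w_prior=1.5)
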