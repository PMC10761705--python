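"""Three-pool forward model, screening, likelihood and MCMC inversion."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from soiltau.kinetics import (activation_energy_from_q10, default_q10,
                              forward_flux, log_likelihood, mh_sample,
                              normalize_arrhenius, normalize_to_reference,
                              screen_records)
from soiltau.synthetic import gen_incubation_series
from soiltau.types import IncubationSeries, PoolParams


def _series(times, fluxes, duration=400.0, c_tot=20.0, **meta):
    md = {"aerobic": True, "substrate_added": False}
    md.update(meta)
    return IncubationSeries("s", np.asarray(times, float), np.asarray(fluxes, float),
                            c_tot, 20.0, duration, md)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

class TestForwardFlux:
    def test_initial_flux_single_pool(self):
        p = PoolParams(k=[0.01, 1e-4, 1e-6], f=[1.0, 0.0, 0.0])
        assert forward_flux(p, 10.0, [0.0])[0] == pytest.approx(0.1, abs=1e-15)

    def test_exponential_depletion(self):
        p = PoolParams(k=[0.01, 1e-4, 1e-6], f=[1.0, 0.0, 0.0])
        assert forward_flux(p, 10.0, [100.0])[0] == pytest.approx(0.1 * np.exp(-1), rel=1e-12)

    def test_matches_ode_integration_oracle(self):
        # independent route: integrate dC_p/dt = -k_p C_p and evaluate sum k_p C_p
        p = PoolParams(k=[0.05, 0.001, 1e-5], f=[0.1, 0.3, 0.6])
        c_tot, t_eval = 20.0, 30.0
        sol = solve_ivp(lambda t, c: -p.k * c, (0, t_eval), p.f * c_tot,
                        rtol=1e-12, atol=1e-14, t_eval=[t_eval])
        oracle = float((p.k * sol.y[:, -1]).sum())
        assert forward_flux(p, c_tot, [t_eval])[0] == pytest.approx(oracle, abs=1e-8)

    def test_monotone_decay_to_zero(self):
        p = PoolParams(k=[0.05, 0.001, 1e-5], f=[0.2, 0.3, 0.5])
        flux = forward_flux(p, 10.0, np.linspace(0, 5000, 200))
        assert np.all(np.diff(flux) < 0) and flux[-1] < flux[0] * 0.1

    def test_mass_exhaustion_integral(self):
        # integral of the flux over [0, inf) must equal C_tot
        p = PoolParams(k=[0.05, 0.001, 1e-5], f=[0.1, 0.3, 0.6])
        c_tot = 20.0
        upper = 30.0 / p.k.min()  # exp(-30) tail is far below the tolerance
        total, _ = quad(lambda t: forward_flux(p, c_tot, [t])[0], 0, upper,
                        points=[1 / ki for ki in p.k], limit=200)
        assert total == pytest.approx(c_tot, rel=1e-6)

    def test_negative_time_rejected(self):
        p = PoolParams(k=[0.05, 0.001, 1e-5], f=[0.1, 0.3, 0.6])
        with pytest.raises(ValueError, match="negative"):
            forward_flux(p, 10.0, [-1.0])

    @pytest.mark.parametrize("k,f", [
        ([0.001, 0.01, 1e-5], [0.1, 0.3, 0.6]),   # wrong ordering
        ([0.05, 0.001, 1e-5], [0.5, 0.3, 0.3]),   # fractions not summing to 1
        ([0.05, 0.001, 1e-5], [1.2, -0.1, -0.1]), # out of range
    ])
    def test_invalid_params_rejected(self, k, f):
        with pytest.raises(ValueError):
            forward_flux(PoolParams(k=k, f=f), 10.0, [0.0])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class TestLogLikelihood:
    p = PoolParams(k=[0.05, 0.001, 1e-5], f=[0.1, 0.3, 0.6])

    def test_brute_force_summation(self):
        times = np.array([0.0, 5.0, 20.0, 100.0, 300.0])
        obs = forward_flux(self.p, 20.0, times) + np.array([0.01, -0.02, 0.005, 0.0, 0.003])
        ser = _series(times, obs)
        sigma = 0.05
        expected = -sum(
            (forward_flux(self.p, 20.0, [t])[0] - o) ** 2 for t, o in zip(times, obs)
        ) / (2 * sigma**2)
        assert log_likelihood(self.p, ser, sigma) == pytest.approx(expected, rel=1e-12)

    def test_zero_residual_is_maximum(self):
        times = np.linspace(0, 400, 30)
        ser = _series(times, forward_flux(self.p, 20.0, times))
        assert log_likelihood(self.p, ser, 0.1) == 0.0
        worse = PoolParams(k=[0.06, 0.001, 1e-5], f=[0.1, 0.3, 0.6])
        assert log_likelihood(worse, ser, 0.1) < 0.0

    def test_quadratic_in_residuals(self):
        times = np.linspace(0, 400, 30)
        model = forward_flux(self.p, 20.0, times)
        r = 0.01 * np.sin(times / 30.0)
        ll1 = log_likelihood(self.p, _series(times, model + r), 0.1)
        ll2 = log_likelihood(self.p, _series(times, model + 2 * r), 0.1)
        assert ll2 == pytest.approx(4 * ll1, rel=1e-12)

    def test_sigma_must_be_positive(self):
        ser = _series([0, 1], [1.0, 0.9])
        with pytest.raises(ValueError):
            log_likelihood(self.p, ser, 0.0)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

class TestScreening:
    def _good(self, **kw):
        times = np.linspace(0, kw.pop("duration", 400.0), 50)
        fluxes = 0.1 * np.exp(-times / 150.0) + 0.01
        return _series(times, fluxes, duration=float(times[-1]), **kw)

    def test_good_record_kept(self):
        kept, rejected = screen_records([self._good()])
        assert len(kept) == 1 and not rejected

    @pytest.mark.parametrize("mutate,reason", [
        (lambda s: setattr(s, "duration", 150.0), "duration"),
        (lambda s: s.metadata.update(aerobic=False), "aerobic"),
        (lambda s: setattr(s, "c_tot", None), "c_tot"),
        (lambda s: s.metadata.update(substrate_added=True), "substrate"),
        (lambda s: setattr(s, "fluxes", s.fluxes[::-1].copy()), "no_decline"),
        (lambda s: setattr(s, "times", None), "unparseable"),
    ])
    def test_first_failing_criterion_reported(self, mutate, reason):
        rec = self._good()
        mutate(rec)
        kept, rejected = screen_records([rec])
        assert not kept and rejected[0][1] == reason

    def test_duration_boundary_six_months(self):
        kept, _ = screen_records([self._good(duration=180.0)])
        assert len(kept) == 1


# ---------------------------------------------------------------------------
# MCMC inversion
# ---------------------------------------------------------------------------

class TestMHSampler:
    def test_same_seed_identical_chains(self, recovery_params):
        ser = gen_incubation_series(recovery_params, 20.0, 20.0, 400.0,
                                    noise_sd=1e-4, seed=0)
        a = mh_sample(ser, n_iter=1500, seed=5)
        b = mh_sample(ser, n_iter=1500, seed=5)
        assert np.array_equal(a.chains, b.chains)
        assert a.acceptance_rate == b.acceptance_rate

    def test_acceptance_rate_in_working_range(self, recovery_params):
        ser = gen_incubation_series(recovery_params, 20.0, 20.0, 730.0,
                                    noise_sd=2e-4, seed=1)
        post = mh_sample(ser, n_iter=4000, seed=2)
        assert 0.05 < post.acceptance_rate < 0.8

    def test_draws_satisfy_constraints(self, recovery_params):
        ser = gen_incubation_series(recovery_params, 20.0, 20.0, 400.0,
                                    noise_sd=2e-4, seed=1)
        post = mh_sample(ser, n_iter=2000, seed=3)
        k, f = post.chains[:, :3], post.chains[:, 3:]
        assert np.all((k[:, 0] > k[:, 1]) & (k[:, 1] > k[:, 2]) & (k[:, 2] > 0))
        assert np.all((f >= 0) & (f <= 1))
        assert np.allclose(f.sum(axis=1), 1.0, atol=1e-9)

    def test_parameter_recovery_within_information_bound(self, recovery_params):
        """Point estimates agree with the truth to within ~3 sigma of the
        Cramer-Rao floor for this design (relative sd ~0.21-0.23 on the
        fast/slow rates at 5%-of-initial-flux noise)."""
        noiseless = gen_incubation_series(recovery_params, 20.0, 20.0, 730.0,
                                          noise_sd=0.0, seed=0)
        noise = 0.05 * noiseless.fluxes[0]
        for seed in (1, 2, 3):
            ser = gen_incubation_series(recovery_params, 20.0, 20.0, 730.0,
                                        noise_sd=noise, seed=seed)
            post = mh_sample(ser, n_iter=20000, seed=seed)
            pt = post.summaries["point"]
            assert abs(pt["k_fast"] - 0.05) / 0.05 < 0.7
            assert abs(pt["k_slow"] - 6e-3) / 6e-3 < 0.7
            for pool, truth in zip(("fast", "slow", "passive"), recovery_params.f):
                assert abs(pt[f"f_{pool}"] - truth) < 0.15

    def test_single_pool_series_assigns_mass_to_fast(self):
        """A noiseless single-pool decay fitted with the three-pool model
        places essentially all carbon in the fast pool at the likelihood
        optimum; the tempered posterior mean (sigma = flux std) is lower
        but still fast-dominated."""
        times = np.arange(0.0, 400.0, 7.0)
        fluxes = 0.02 * 20.0 * np.exp(-0.02 * times)
        ser = _series(times, fluxes, duration=400.0)
        post = mh_sample(ser, n_iter=20000, seed=0)
        assert post.summaries["point"]["f_fast"] > 0.9
        assert post.summaries["mean"]["f_fast"] > 0.6

    def test_posterior_width_shrinks_with_duration(self, recovery_params):
        """Longer incubations inform the slow pool: the k_slow credible
        interval at 4 yr is narrower than at 0.5 yr for the same noise."""
        noiseless = gen_incubation_series(recovery_params, 20.0, 20.0, 183.0,
                                          noise_sd=0.0, seed=0)
        noise = float(0.03 * noiseless.fluxes[0])
        priors = {"k_slow": (1e-5, 5e-2)}
        widths = {}
        for dur in (183.0, 1461.0):
            per_seed = []
            for seed in (4, 5, 6):
                ser = gen_incubation_series(recovery_params, 20.0, 20.0, dur,
                                            noise_sd=noise, seed=seed)
                post = mh_sample(ser, priors=priors, n_iter=8000, seed=seed,
                                 sigma=noise)
                lo, hi = post.summaries["ci"]["k_slow"]
                per_seed.append(hi - lo)
            widths[dur] = per_seed
        assert max(widths[1461.0]) < min(widths[183.0])

    def test_zero_variance_series_rejected(self):
        ser = _series(np.arange(5.0), np.full(5, 0.1))
        with pytest.raises(ValueError, match="sigma undefined"):
            mh_sample(ser, n_iter=1000, seed=0)

    def test_infeasible_priors_rejected(self, recovery_params):
        ser = gen_incubation_series(recovery_params, 20.0, 20.0, 400.0,
                                    noise_sd=1e-4, seed=0)
        with pytest.raises(ValueError, match="ordering"):
            mh_sample(ser, priors={"k_fast": (1e-6, 1e-5), "k_slow": (1e-2, 1e-1)},
                      n_iter=1000, seed=0)

    def test_minimum_iterations_enforced(self, recovery_params):
        ser = gen_incubation_series(recovery_params, 20.0, 20.0, 400.0,
                                    noise_sd=1e-4, seed=0)
        with pytest.raises(ValueError):
            mh_sample(ser, n_iter=500, seed=0)


# ---------------------------------------------------------------------------
# temperature normalization
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_reference_temperature_identity(self):
        assert normalize_to_reference(3.7, 15.0) == pytest.approx(3.7, rel=1e-14)

    @pytest.mark.parametrize("tau,t_inc,expected", [(2.0, 25.0, 4.0), (2.0, 5.0, 1.0)])
    def test_constant_q10_scaling(self, tau, t_inc, expected):
        out = normalize_to_reference(tau, t_inc, q10_fn=lambda t: 2.0)
        assert out == pytest.approx(expected, rel=1e-12)

    def test_default_q10_decreases_with_temperature(self):
        q = default_q10(np.array([0.0, 15.0, 35.0]))
        assert q[0] == pytest.approx(3.0) and q[2] == pytest.approx(1.8)
        assert np.all(np.diff(q) < 0)

    def test_nonpositive_q10_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference(2.0, 25.0, q10_fn=lambda t: -1.0)

    def test_activation_energy_reproduces_centered_q10(self):
        # Arrhenius ratio over [T-5, T+5] equals the Q10 it was built from
        for t in (10.0, 20.0, 30.0):
            ea = activation_energy_from_q10(2.3, t)
            ratio = (normalize_arrhenius(1.0, t + 5.0, ea)
                     / normalize_arrhenius(1.0, t - 5.0, ea))
            assert ratio == pytest.approx(2.3, rel=1e-12)

    def test_arrhenius_matches_q10_locally(self):
        # matched at the incubation temperature, the two normalizations
        # agree closely for moderate offsets from the reference
        for t_inc in (10.0, 20.0, 25.0):
            q10 = float(default_q10(t_inc))
            ea = activation_energy_from_q10(q10, t_inc)
            a = normalize_arrhenius(2.0, t_inc, ea)
            b = normalize_to_reference(2.0, t_inc, q10_fn=default_q10)
            assert a == pytest.approx(b, rel=0.06)
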