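import json

import numpy as np
import pytest

from hhabc.abc_smc import (
    KernelSpec,
    Population,
    PriorSpec,
    ScheduleState,
    advance_schedule,
    default_kernel,
    default_prior,
    distance_multi,
    distance_single,
    param_names_for,
    perturb,
    run_abc_smc,
    sample_prior,
)
from hhabc.model import VoltageDependencyParams, rates_from_voltage
from hhabc.pipeline import _constant_rate_conductance
from hhabc.protocols import ConductanceTrace


def _trace(t, g, species="K", depol=40.0):
    return ConductanceTrace(t=np.asarray(t, float), g=np.asarray(g, float),
                            species=species, depolarization_mV=depol)


class TestDistances:
    def test_identical_traces_zero(self):
        a = _trace([0, 1, 2], [1.0, 2.0, 3.0])
        assert distance_single(a, a) == 0.0

    def test_constant_offset(self):
        a = _trace([0, 1, 2], [1.0, 2.0, 3.0])
        b = _trace([0, 1, 2], [1.5, 2.5, 3.5])
        assert distance_single(a, b) == pytest.approx(0.5)

    def test_three_point_hand_value(self):
        a = _trace([0, 1, 2], [1.0, 2.0, 3.0])
        b = _trace([0, 1, 2], [1.0, 2.0, 5.0])
        assert distance_single(a, b) == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_squared_option_is_mse(self):
        a = _trace([0, 1, 2], [1.0, 2.0, 3.0])
        b = _trace([0, 1, 2], [1.0, 2.0, 5.0])
        assert distance_single(a, b, squared=True) == pytest.approx(4.0 / 3.0)

    def test_grid_mismatch_raises(self):
        a = _trace([0, 1, 2], [1.0, 2.0, 3.0])
        b = _trace([0, 1, 2.5], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            distance_single(a, b)

    def test_multi_single_pair_equals_single(self):
        a = _trace([0, 1], [1.0, 2.0])
        b = _trace([0, 1], [2.0, 3.0])
        assert distance_multi([a], [b]) == distance_single(a, b)

    def test_multi_duplicate_pair_invariant(self):
        a = _trace([0, 1], [1.0, 2.0])
        b = _trace([0, 1], [2.0, 3.0])
        assert distance_multi([a, a], [b, b]) == pytest.approx(
            distance_single(a, b))

    def test_multi_is_arithmetic_mean(self):
        a1, b1 = _trace([0], [0.0]), _trace([0], [1.0])   # RMSE 1
        a2, b2 = _trace([0], [0.0]), _trace([0], [3.0])   # RMSE 3
        assert distance_multi([a1, a2], [b1, b2]) == pytest.approx(2.0)

    def test_multi_empty_raises(self):
        with pytest.raises(ValueError):
            distance_multi([], [])


class TestPriorAndKernel:
    def test_default_prior_contains_reported_values(self):
        k = VoltageDependencyParams()
        for species in ("K", "Na"):
            names = param_names_for("full", species)
            prior = default_prior(names)
            theta = np.array([getattr(k, n) for n in names])
            assert prior.contains(theta)

    def test_reported_rates_inside_simplified_priors(self, k_default):
        r = rates_from_voltage(k_default, -40.0)
        prior = default_prior(param_names_for("simplified", "Na"))
        theta = np.array([r.alpha_m, r.beta_m, r.alpha_h, r.beta_h])
        assert prior.contains(theta)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(names=("a",), lower=np.array([1.0]), upper=np.array([1.0]))

    def test_samples_within_bounds(self):
        prior = default_prior(("alpha_n", "beta_n"))
        rng = np.random.default_rng(0)
        draws = np.array([sample_prior(prior, rng) for _ in range(500)])
        assert np.all(draws >= 0.0) and np.all(draws <= 1.0)

    def test_sample_mean_matches_midpoint(self):
        prior = PriorSpec(names=("x",), lower=np.array([2.0]),
                          upper=np.array([6.0]))
        rng = np.random.default_rng(1)
        draws = np.array([sample_prior(prior, rng)[0] for _ in range(100_000)])
        se = (6.0 - 2.0) / np.sqrt(12 * len(draws))
        assert abs(draws.mean() - 4.0) < 3 * se

    def test_kernel_requires_positive_variance(self):
        with pytest.raises(ValueError):
            KernelSpec(variances=np.array([0.0]))

    def test_perturb_tiny_kernel_stays_close(self):
        prior = default_prior(("alpha_n",))
        kernel = KernelSpec(variances=np.array([1e-20]))
        rng = np.random.default_rng(0)
        theta = np.array([0.5])
        out = perturb(theta, kernel, prior, rng)
        assert out[0] == pytest.approx(0.5, abs=1e-8)

    def test_perturb_from_bound_stays_in_support(self):
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        rng = np.random.default_rng(0)
        for _ in range(200):
            out = perturb(np.array([0.0]), kernel, prior, rng)
            assert prior.contains(out)

    def test_truncation_shrinks_empirical_variance(self):
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))     # variance 0.1
        rng = np.random.default_rng(2)
        deltas = np.array([perturb(np.array([0.05]), kernel, prior, rng)[0] - 0.05
                           for _ in range(5000)])
        assert deltas.var() <= 0.1

    def test_perturb_outside_support_rejected(self):
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        with pytest.raises(ValueError):
            perturb(np.array([2.0]), kernel, prior, np.random.default_rng(0))


class TestAdaptiveSchedule:
    def _state(self, eps_t, eps_prev, tau=0.003):
        return ScheduleState(epsilon_t=eps_t, epsilon_prev=eps_prev,
                             delta_eps=eps_t - eps_prev, tau=tau,
                             max_draws=1000)

    def test_success_halves(self):
        nxt = advance_schedule(self._state(1.0, 2.0), succeeded=True)
        assert nxt.epsilon_t == pytest.approx(0.5)
        assert nxt.epsilon_prev == pytest.approx(1.0)

    def test_failure_backtracks_halfway(self):
        nxt = advance_schedule(self._state(0.5, 1.0), succeeded=False)
        assert nxt.epsilon_t == pytest.approx(0.75)

    def test_small_delta_terminates(self):
        assert advance_schedule(self._state(0.998, 1.0), succeeded=False) is None

    def test_hand_traced_failure_sequence(self):
        # repeated failures: 0.5, 0.75, 0.875, ... -> terminate
        state = self._state(0.5, 1.0, tau=0.07)
        seen = [state.epsilon_t]
        while state is not None:
            state = advance_schedule(state, succeeded=False)
            if state is not None:
                seen.append(state.epsilon_t)
        np.testing.assert_allclose(seen, [0.5, 0.75, 0.875, 0.9375])
        # next delta would be 0.03125 < 0.07 -> terminated


def _toy_observed(depol=88.0):
    """Noiseless single-gate potassium clamp trace from reported rates."""
    k = VoltageDependencyParams()
    r = rates_from_voltage(k, -depol)
    t = np.linspace(0, 12, 121)
    from hhabc.model import MembraneConstants
    g = _constant_rate_conductance((r.alpha_n, r.beta_n),
                                   ("alpha_n", "beta_n"), "K", t,
                                   MembraneConstants())
    return _trace(t, g, "K", depol), r


def _one_param_simulator(observed, beta_fixed):
    from hhabc.model import MembraneConstants
    consts = MembraneConstants()

    def sim(theta):
        g = _constant_rate_conductance((theta[0], beta_fixed),
                                       ("alpha_n", "beta_n"), "K",
                                       observed.t, consts)
        return float(np.sqrt(np.mean((observed.g - g) ** 2)))

    return sim


class TestRunAbcSmc:
    def test_huge_tau_terminates_immediately(self):
        observed, r = _toy_observed()
        sim = _one_param_simulator(observed, r.beta_n)
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        res = run_abc_smc(sim, prior, kernel, n_particles=10, max_draws=200,
                          tau=1e9, rng=np.random.default_rng(0))
        assert len(res.populations) <= 2
        for pop in res.populations:
            assert pop.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_one_param_recovery(self):
        observed, r = _toy_observed()
        sim = _one_param_simulator(observed, r.beta_n)
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        res = run_abc_smc(sim, prior, kernel, n_particles=50, max_draws=2000,
                          tau=0.003, rng=np.random.default_rng(3))
        final = res.final
        mean = float(np.average(final.thetas[:, 0], weights=final.weights))
        assert mean == pytest.approx(r.alpha_n, rel=0.05)
        assert np.all(final.distances <= final.epsilon)

    def test_sampler_invariants(self):
        observed, r = _toy_observed()
        sim = _one_param_simulator(observed, r.beta_n)
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        res = run_abc_smc(sim, prior, kernel, n_particles=20, max_draws=500,
                          tau=0.05, rng=np.random.default_rng(7))
        eps = [p.epsilon for p in res.populations[1:]]
        assert all(b < a for a, b in zip(eps, eps[1:]))      # strict decrease
        for pop in res.populations:
            assert pop.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(pop.weights >= 0)
            for i in range(pop.size):
                assert prior.contains(pop.thetas[i])
            if pop.generation >= 1:
                assert np.all(pop.distances <= pop.epsilon)

    def test_seeded_determinism_byte_level(self):
        observed, r = _toy_observed()
        sim = _one_param_simulator(observed, r.beta_n)
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        outs = []
        for _ in range(2):
            res = run_abc_smc(sim, prior, kernel, n_particles=15,
                              max_draws=300, tau=0.05,
                              rng=np.random.default_rng(11))
            outs.append("".join(p.to_json() for p in res.populations))
        assert outs[0] == outs[1]

    def test_rejection_sampler_equivalence_single_generation(self):
        # with a fixed epsilon and one conditioned generation, the accepted
        # particles are exactly the D <= eps prefix of the proposal stream
        observed, r = _toy_observed()
        base = _one_param_simulator(observed, r.beta_n)
        log = []

        def recording_sim(theta):
            d = base(theta)
            log.append((float(theta[0]), d))
            return d

        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        eps0 = 8.0
        res = run_abc_smc(recording_sim, prior, kernel, n_particles=10,
                          max_draws=500, tau=1e9, epsilon0=eps0,
                          rng=np.random.default_rng(5), max_generations=1)
        assert len(res.populations) == 2
        gen1 = res.populations[1]
        assert gen1.epsilon == pytest.approx(0.5 * eps0)
        proposals = log[res.populations[0].n_draws:]
        accepted = [th for th, d in proposals if d <= gen1.epsilon][:10]
        np.testing.assert_allclose(gen1.thetas[:, 0], accepted)

    def test_simulator_failures_are_rejections(self):
        observed, r = _toy_observed()
        base = _one_param_simulator(observed, r.beta_n)
        calls = {"n": 0}

        def flaky(theta):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("synthetic integration failure")
            return base(theta)

        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        res = run_abc_smc(flaky, prior, kernel, n_particles=10, max_draws=500,
                          tau=0.5, rng=np.random.default_rng(9))
        for pop in res.populations:
            assert np.all(np.isfinite(pop.distances))

    def test_bad_arguments_rejected(self):
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        with pytest.raises(ValueError):
            run_abc_smc(lambda th: 0.0, prior, kernel, n_particles=1,
                        max_draws=10, tau=0.1, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            run_abc_smc(lambda th: 0.0, prior, kernel, n_particles=5,
                        max_draws=10, tau=0.0, rng=np.random.default_rng(0))


class TestResultCsvSerialization:
    def test_write_csv_layout_and_metadata(self, tmp_path):
        observed, r = _toy_observed()
        sim = _one_param_simulator(observed, r.beta_n)
        prior = default_prior(("alpha_n",))
        kernel = default_kernel(("alpha_n",))
        res = run_abc_smc(sim, prior, kernel, n_particles=6, max_draws=200,
                          tau=0.5, rng=np.random.default_rng(21), seed=21)
        csv_path = tmp_path / "pops.csv"
        res.write_csv(csv_path)
        lines = csv_path.read_text().splitlines()
        assert lines[0] == "generation,particle_id,weight,distance,alpha_n"
        assert len(lines) == 1 + 6 * len(res.populations)
        meta = json.loads((tmp_path / "pops.meta.json").read_text())
        assert meta["seed"] == 21
        assert meta["epsilon_history"][0] is None
        assert meta["param_names"] == ["alpha_n"]


class TestPopulationSerialization:
    def test_json_roundtrip(self):
        pop = Population(thetas=np.array([[0.1, 0.2], [0.3, 0.4]]),
                         weights=np.array([0.5, 0.5]),
                         distances=np.array([1.0, 2.0]),
                         epsilon=2.5, generation=3, n_draws=17,
                         param_names=("alpha_n", "beta_n"))
        back = Population.from_json(pop.to_json())
        np.testing.assert_array_equal(back.thetas, pop.thetas)
        np.testing.assert_array_equal(back.weights, pop.weights)
        assert back.epsilon == pop.epsilon
        assert back.param_names == pop.param_names
        assert json.loads(pop.to_json())["generation"] == 3
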