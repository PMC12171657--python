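"""Monte Carlo engine: trial mechanics, determinism, and analytic agreement."""

import numpy as np
import pytest

from darkfigure.analytic import population_rates
from darkfigure.hazard import DesistanceSchedule, trajectory_matrix
from darkfigure.montecarlo import run_mc, simulate_trial
from darkfigure.scenario import RateEstimates, ScenarioSpec, TrialOutcome

HEADLINE = DesistanceSchedule(0.123)


def make_spec(**kwargs):
    defaults = dict(mu=0.1, r=0.5, schedule=HEADLINE, n_iterations=5000, seed=7)
    defaults.update(kwargs)
    return ScenarioSpec(**defaults)


class TestScenarioSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu": 0.0},
            {"r": 1.5},
            {"checkpoints": (5, 30)},
            {"checkpoints": (10, 5)},
            {"n_iterations": 0},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            make_spec(**kwargs)

    def test_dict_round_trip(self):
        spec = make_spec()
        assert ScenarioSpec.from_dict(spec.to_dict()) == spec


class TestTrialOutcome:
    def test_charge_before_offense_rejected(self):
        with pytest.raises(ValueError):
            TrialOutcome(first_offense_year=5, first_charge_year=3)
        with pytest.raises(ValueError):
            TrialOutcome(first_offense_year=None, first_charge_year=3)


class TestSimulateTrial:
    def test_zero_hazard_never_offends(self):
        rng = np.random.default_rng(0)
        out = simulate_trial(0.0, make_spec(), rng)
        assert out.first_offense_year is None and out.first_charge_year is None

    def test_zero_charge_rate_never_charges(self):
        rng = np.random.default_rng(1)
        spec = make_spec(r=0.0, mu=2.0)
        for _ in range(50):
            assert simulate_trial(2.0, spec, rng).first_charge_year is None

    def test_full_charging_matches_first_offense(self):
        rng = np.random.default_rng(2)
        spec = make_spec(r=1.0)
        for _ in range(200):
            out = simulate_trial(0.8, spec, rng)
            assert out.first_charge_year == out.first_offense_year


class TestRunMC:
    def test_seed_determinism(self):
        spec = make_spec()
        a, b = run_mc(spec), run_mc(spec)
        np.testing.assert_array_equal(a.actual_rate, b.actual_rate)
        np.testing.assert_array_equal(a.charged_rate, b.charged_rate)

    def test_different_seeds_differ(self):
        a = run_mc(make_spec(seed=1))
        b = run_mc(make_spec(seed=2))
        assert not np.array_equal(a.actual_rate, b.actual_rate)

    def test_rate_structure(self):
        est = run_mc(make_spec(n_iterations=20000))
        assert est.method == "monte_carlo"
        assert np.all(np.diff(est.actual_rate) >= 0)  # cumulative
        assert np.all(est.actual_rate >= est.charged_rate)
        assert np.all((est.actual_rate >= 0) & (est.actual_rate <= 1))

    def test_full_charging_equates_actual_and_charged(self):
        est = run_mc(make_spec(r=1.0, n_iterations=20000))
        np.testing.assert_array_equal(est.actual_rate, est.charged_rate)

    def test_vanishing_hazard_gives_near_zero_rates(self):
        est = run_mc(make_spec(mu=1e-9, n_iterations=10000))
        assert np.all(est.actual_rate <= 1e-3)

    @pytest.mark.parametrize("r", [1.0, 0.5, 0.05])
    @pytest.mark.parametrize("d", [0.0, 0.123, 0.2])
    def test_agrees_with_analytic_oracle(self, r, d):
        """MC checkpoint rates lie within 3 SE of the quadrature values."""
        sched = DesistanceSchedule(d)
        spec = make_spec(mu=0.08, r=r, schedule=sched, n_iterations=30000, seed=11)
        mc = run_mc(spec)
        ana = population_rates(0.08, r, sched)
        se = np.maximum(mc.actual_se, 1e-6)
        assert np.all(np.abs(mc.actual_rate - ana.actual_rate) <= 3 * se)
        se_c = np.maximum(mc.charged_se, 1e-6)
        assert np.all(np.abs(mc.charged_rate - ana.charged_rate) <= 3 * se_c)

    def test_thinning_equivalence(self):
        """Binomial thinning of Poisson counts matches direct Poisson(r*lambda)."""
        spec = make_spec(mu=0.15, r=0.3, n_iterations=30000, seed=5)
        mc = run_mc(spec)
        # independent direct simulation of charged counts
        rng = np.random.default_rng(99)
        lam1 = rng.exponential(spec.mu, spec.n_iterations)
        lams = trajectory_matrix(lam1, spec.schedule, spec.T)
        charged = rng.poisson(spec.r * lams)
        charged_by = np.cumsum(charged >= 1, axis=1) >= 1
        idx = [c - 1 for c in spec.checkpoints]
        direct = charged_by[:, idx].mean(axis=0)
        se = np.sqrt(mc.charged_se**2 + direct * (1 - direct) / spec.n_iterations)
        assert np.all(np.abs(mc.charged_rate - direct) <= 3 * np.maximum(se, 1e-6))

    def test_monotone_in_mu_at_matched_seed(self):
        rates = [
            run_mc(make_spec(mu=mu, n_iterations=20000, seed=3)).actual_rate
            for mu in (0.02, 0.05, 0.1, 0.3)
        ]
        for lo, hi in zip(rates, rates[1:]):
            assert np.all(hi >= lo)

    def test_trial_and_vectorized_paths_agree_in_distribution(self):
        """The scalar reference trial and vectorized engine estimate the same rates."""
        spec = make_spec(mu=0.2, r=0.5, n_iterations=4000, seed=13, checkpoints=(5, 25))
        rng = np.random.default_rng(spec.seed + 1)
        lam1 = rng.exponential(spec.mu, spec.n_iterations)
        hits = np.zeros(2)
        for lam in lam1:
            out = simulate_trial(lam, spec, rng)
            for j, cp in enumerate(spec.checkpoints):
                if out.first_offense_year is not None and out.first_offense_year <= cp:
                    hits[j] += 1
        scalar_rates = hits / spec.n_iterations
        vec = run_mc(spec)
        se = np.sqrt(vec.actual_se**2 + scalar_rates * (1 - scalar_rates) / spec.n_iterations)
        assert np.all(np.abs(scalar_rates - vec.actual_rate) <= 3 * np.maximum(se, 1e-6))


class TestRateEstimatesAccessors:
    def test_checkpoint_lookup(self):
        est = run_mc(make_spec())
        assert est.actual_at(25) == est.actual_rate[-1]
        with pytest.raises(ValueError):
            est.actual_at(7)
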