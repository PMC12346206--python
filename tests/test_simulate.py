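"""Monte Carlo engine: degenerate limits, reproducibility, oracle means,
sensitivity, convergence diagnostics."""

import numpy as np
import pytest

from handcost import (
    ConfigurationError,
    DistributionSpec,
    ScenarioModel,
    convergence_report,
    run_simulation,
)


def _point(name, value):
    return DistributionSpec(
        name, "triangular", {"min": value, "mode": value, "max": value}
    )


def _degenerate_model(reinfect_p, **kwargs):
    inputs = {
        "hospitalization_cost": _point("hospitalization_cost", 1000.0),
        "surgical_cost": _point("surgical_cost", 2000.0),
        "antibiotic_days": _point("antibiotic_days", 12.0),
        "reinfection_rate": DistributionSpec(
            "reinfection_rate", "bernoulli", {"p": reinfect_p}
        ),
        "lost_workdays": _point("lost_workdays", 5.0),
    }
    return ScenarioModel(
        inputs=inputs,
        antibiotic_cost_per_day=10.0,
        reinfection_episode_cost=500.0,
        daily_wage=20.0,
        n_iterations=kwargs.pop("n_iterations", 500),
        **kwargs,
    )


class TestDegenerateLimit:
    def test_point_masses_give_exact_linear_composition(self, identity_tables):
        """All-point-mass inputs: every iteration total equals the
        hand-computed composition 1000+2000+12*10+0*500+5*20 = 3220."""
        result = run_simulation(_degenerate_model(0.0), identity_tables)
        assert np.all(result.iteration_totals == 3220.0)
        assert result.mean_total == 3220.0
        assert result.ci95 == (3220.0, 3220.0)

    def test_certain_reinfection_adds_episode_cost(self, identity_tables):
        result = run_simulation(_degenerate_model(1.0), identity_tables)
        assert np.all(result.iteration_totals == 3720.0)

    def test_currency_conversion_applied_after_composition(self, toy_tables):
        model = _degenerate_model(0.0, year=2020)
        result = run_simulation(model, toy_tables)
        # 3220 TRY -> /5 fx -> *1.2 CPI
        assert np.allclose(result.iteration_totals, 3220.0 / 5 * 1.2)


class TestReproducibility:
    def test_same_seed_bit_identical(self, tables):
        a = run_simulation(ScenarioModel(seed=11, n_iterations=2000), tables)
        b = run_simulation(ScenarioModel(seed=11, n_iterations=2000), tables)
        assert np.array_equal(a.iteration_totals, b.iteration_totals)
        assert a.mean_total == b.mean_total
        assert a.ci95 == b.ci95
        assert a.sensitivity == b.sensitivity

    def test_different_seed_differs(self, tables):
        a = run_simulation(ScenarioModel(seed=11, n_iterations=2000), tables)
        c = run_simulation(ScenarioModel(seed=12, n_iterations=2000), tables)
        assert not np.array_equal(a.iteration_totals, c.iteration_totals)


def test_hospitalization_only_reduces_to_triangular_mean(identity_tables):
    """With all coefficients zero and every other input degenerate at zero,
    the mean total is the triangular mean (8000+12000+18000)/3."""
    inputs = {
        "hospitalization_cost": DistributionSpec(
            "hospitalization_cost", "triangular",
            {"min": 8000, "mode": 12000, "max": 18000},
        ),
        "surgical_cost": _point("surgical_cost", 0.0),
        "antibiotic_days": _point("antibiotic_days", 0.0),
        "reinfection_rate": DistributionSpec(
            "reinfection_rate", "bernoulli", {"p": 0.0}
        ),
        "lost_workdays": _point("lost_workdays", 0.0),
    }
    model = ScenarioModel(
        inputs=inputs, antibiotic_cost_per_day=0.0,
        reinfection_episode_cost=0.0, daily_wage=0.0,
        n_iterations=10_000, seed=5,
    )
    result = run_simulation(model, identity_tables)
    expected = (8000 + 12000 + 18000) / 3
    sd = np.sqrt(model.inputs["hospitalization_cost"].var())
    assert abs(result.mean_total - expected) < 3 * sd / np.sqrt(10_000)


def test_zero_coefficient_input_has_null_sensitivity(identity_tables):
    """An input whose coefficient is zero is independent of the total:
    |rho| below the 4/sqrt(n) noise band."""
    model = ScenarioModel(daily_wage=0.0, n_iterations=10_000, seed=6)
    result = run_simulation(model, identity_tables)
    assert abs(result.sensitivity["lost_workdays"]) < 4 / np.sqrt(10_000)
    # the dominant cost driver is strongly rank-correlated
    assert result.sensitivity["hospitalization_cost"] > 0.3


def test_percentile_ci_contains_mean_default_scenario(tables):
    result = run_simulation(ScenarioModel(seed=3), tables)
    lo, hi = result.ci95
    assert lo <= result.mean_total <= hi
    assert len(result.iteration_totals) == result.n_iterations == 10_000


class TestScenarioValidation:
    def test_missing_canonical_input_rejected(self):
        from handcost.simulate import default_inputs

        inputs = default_inputs()
        del inputs["lost_workdays"]
        with pytest.raises(ConfigurationError, match="lost_workdays"):
            ScenarioModel(inputs=inputs)

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioModel(n_iterations=1)

    def test_generator_families_not_allowed_as_inputs(self):
        from handcost.simulate import default_inputs

        inputs = default_inputs()
        inputs["hospitalization_cost"] = DistributionSpec(
            "hospitalization_cost", "lognormal", {"mean": 100, "sd": 10}
        )
        with pytest.raises(ConfigurationError, match="family"):
            ScenarioModel(inputs=inputs)


class TestConvergence:
    def test_degenerate_half_width_zero(self, identity_tables):
        result = run_simulation(_degenerate_model(0.0), identity_tables)
        df = convergence_report(result, batch_size=100)
        assert (df["ci95_half_width"] == 0.0).all()
        assert df.attrs["converged"]

    def test_half_width_scales_like_inverse_sqrt_n(self, tables):
        result = run_simulation(ScenarioModel(seed=9), tables)
        df = convergence_report(result, batch_size=100).set_index("n")
        ratio = df.loc[100, "ci95_half_width"] / df.loc[10_000, "ci95_half_width"]
        assert 7 < ratio < 13  # ~ sqrt(10_000/100) = 10
        mid = df.loc[1000, "ci95_half_width"] / df.loc[10_000, "ci95_half_width"]
        assert 2 < mid < 4.5  # ~ sqrt(10) = 3.16

    def test_same_seed_identical_reports(self, tables):
        r1 = run_simulation(ScenarioModel(seed=4, n_iterations=2000), tables)
        r2 = run_simulation(ScenarioModel(seed=4, n_iterations=2000), tables)
        assert convergence_report(r1, 200).equals(convergence_report(r2, 200))

    def test_oversized_batch_rejected(self, tables):
        result = run_simulation(ScenarioModel(seed=4, n_iterations=200), tables)
        with pytest.raises(ConfigurationError):
            convergence_report(result, batch_size=150)


def test_yaml_scenario_round_trip(tmp_path, tables):
    from handcost import load_scenario

    cfg = tmp_path / "scenario.yaml"
    cfg.write_text(
        """
inputs:
  hospitalization_cost: {family: triangular, params: {min: 9000, mode: 12000, max: 15000}, units: TRY}
coefficients: {daily_wage: 350.0}
n_iterations: 500
seed: 21
"""
    )
    model = load_scenario(cfg)
    assert model.inputs["hospitalization_cost"].params["min"] == 9000
    assert model.daily_wage == 350.0
    assert model.n_iterations == 500 and model.seed == 21
    # untouched inputs keep their base-case definitions
    assert model.inputs["reinfection_rate"].params == {"alpha": 3, "beta": 20}
    result = run_simulation(model, tables)
    assert len(result.iteration_totals) == 500
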