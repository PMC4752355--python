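"""Synthetic cohort generator: marginals, determinism, model fidelity."""

import numpy as np
import pandas as pd
import pytest

from crisisrx import ddd as ddd_mod
from crisisrx.synthetic import (
    CohortConfig,
    ConfigError,
    ParameterSet,
    _default_marginals,
    generate_individuals,
    simulate_cohort,
    simulate_panel,
)

from .conftest import small_cohort_config


class TestGenerateIndividuals:
    def test_degenerate_marginal_all_women(self):
        cfg = small_cohort_config(
            covariate_marginals={**_default_marginals(), "female": 1.0})
        ind = generate_individuals(cfg)
        assert (ind["sex"] == "female").all()

    def test_default_marginals_recovered_at_n10000(self):
        cfg = CohortConfig(n_individuals=10_000, seed=5)
        ind = generate_individuals(cfg)
        m = cfg.covariate_marginals
        # women share matches the configured two-thirds within 1.5 points
        assert abs((ind["sex"] == "female").mean() - m["female"]) < 0.015
        # binomial 99% bounds (2.58 sd) for the other proportions
        for value, target in [
            ((ind["family_in_cohort"]).mean(), m["family_in_cohort"]),
            ((~ind["pre2009_consumer"]).mean(), m["control_share"]),
            ((ind["country"] == "spain").mean(), m["country"]["spain"]),
            ((ind["country"] == "maghreb").mean(), m["country"]["maghreb"]),
        ]:
            bound = 2.58 * np.sqrt(target * (1 - target) / 10_000)
            assert abs(value - target) < max(bound, 1e-3)

    def test_age_distribution_moments(self):
        ind = generate_individuals(CohortConfig(n_individuals=10_000, seed=6))
        age0 = 2005 - ind["birth_date"].dt.year
        assert abs(age0.mean() - 54.37) < 1.5
        assert (age0 >= 14).all()

    def test_deterministic_given_seed(self):
        cfg = small_cohort_config()
        pd.testing.assert_frame_equal(generate_individuals(cfg), generate_individuals(cfg))

    def test_invalid_marginals_raise(self):
        bad = {**_default_marginals(), "female": 1.4}
        with pytest.raises(ConfigError):
            small_cohort_config(covariate_marginals=bad)
        country = dict(_default_marginals()["country"])
        country["spain"] += 0.5
        with pytest.raises(ConfigError):
            small_cohort_config(
                covariate_marginals={**_default_marginals(), "country": country})

    def test_config_invariants(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_individuals=1)
        with pytest.raises(ConfigError):
            CohortConfig(n_individuals=10, months=[3, 2, 1])
        with pytest.raises(ConfigError):
            ParameterSet("poisson_count", {}, sigma_b=-0.1)
        with pytest.raises(ConfigError):
            ParameterSet("negbin", {})


class TestSimulatePanel:
    def test_null_model_poisson_mean_one(self):
        """All betas zero, no random effects: Y ~ Poisson(1)."""
        cfg = small_cohort_config(
            n_individuals=400,
            keep_zero_rows=True,
            covariate_marginals={**_default_marginals(), "control_share": 0.0},
            params_count=ParameterSet("poisson_count", {}, 0.0, 0.0, 0.0),
        )
        sim = simulate_cohort(cfg)
        mean = sim.panel["n_drugs"].mean()
        n = len(sim.panel)
        assert abs(mean - 1.0) < 4 / np.sqrt(n)

    def test_post2009_shift_monte_carlo(self):
        """Planted step of log(1.14): ratio of empirical means ~ 1.14."""
        cfg = small_cohort_config(
            n_individuals=2000,
            keep_zero_rows=True,
            covariate_marginals={**_default_marginals(), "control_share": 0.0},
            params_count=ParameterSet(
                "poisson_count", {"const": 0.0, "post2009": float(np.log(1.14))},
                0.0, 0.0, 0.0),
        )
        sim = simulate_cohort(cfg)
        p = sim.panel
        pre = p.loc[p["month"] < cfg.crisis_month, "n_drugs"].mean()
        post = p.loc[p["month"] >= cfg.crisis_month, "n_drugs"].mean()
        assert post / pre == pytest.approx(1.14, abs=0.02)

    def test_rw1_path_serial_correlation(self):
        """A large-innovation RW1 path wanders: lag-1 autocorrelation > 0.9."""
        cfg = small_cohort_config(
            params_count=ParameterSet(
                "poisson_count", {}, sigma_b=0.0, sigma_alpha=0.3, phi=0.0),
        )
        sim = simulate_cohort(cfg)
        path = sim.truth["count"]["alpha"][0]
        r = np.corrcoef(path[:-1], path[1:])[0, 1]
        assert r > 0.9
        assert abs(path.mean()) < 1e-10  # sum-to-zero constraint

    def test_round_trip_through_ddd_aggregation(self, small_sim):
        """aggregate_monthly on emitted records recovers the panel exactly."""
        agg = ddd_mod.aggregate_monthly(small_sim.prescriptions)
        merged = small_sim.panel.merge(
            agg, on=["individual_id", "month"], suffixes=("", "_agg"))
        assert len(merged) == len(small_sim.panel)
        assert (merged["n_drugs"] == merged["n_drugs_agg"]).all()
        np.testing.assert_array_equal(merged["ddd"], merged["ddd_agg"])

    def test_controls_never_consume_pre_crisis(self, small_sim):
        panel = small_sim.panel
        controls = ~small_sim.individuals.set_index("individual_id")["pre2009_consumer"]
        pre = panel[panel["month"] < small_sim.config.crisis_month]
        assert not pre["individual_id"].map(controls).any()

    def test_consumer_months_have_at_least_one_drug(self, small_sim):
        assert (small_sim.panel["n_drugs"] >= 1).all()
        assert (small_sim.panel["ddd"] >= 0).all()

    def test_seeded_determinism_end_to_end(self):
        cfg = small_cohort_config(n_individuals=50)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.panel, b.panel)
        pd.testing.assert_frame_equal(a.prescriptions, b.prescriptions)

    def test_ramp_effect_shape_grows_over_post_period(self):
        cfg = small_cohort_config(
            n_individuals=800, keep_zero_rows=True, effect_shape="ramp",
            covariate_marginals={**_default_marginals(), "control_share": 0.0},
            params_count=ParameterSet(
                "poisson_count", {"const": 0.0, "post2009": 1.0}, 0.0, 0.0, 0.0),
        )
        sim = simulate_cohort(cfg)
        by_month = sim.panel.groupby("month")["n_drugs"].mean()
        early_post = by_month.loc[49:60].mean()
        late_post = by_month.loc[85:96].mean()
        assert late_post > early_post > by_month.loc[1:48].mean()

    def test_time_varying_age_group(self):
        """Individuals crossing a decade boundary change age group."""
        cfg = small_cohort_config(n_individuals=500, keep_zero_rows=True)
        sim = simulate_cohort(cfg)
        changes = sim.panel.groupby("individual_id")["age_group"].nunique()
        assert (changes > 1).any()
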