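"""Design construction and the panel GLMM sampler."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from crisisrx.model import (
    DesignError,
    ModelSpec,
    NotConvergedError,
    PanelGLMM,
    build_design,
    summarize,
)
from crisisrx.synthetic import ParameterSet, _default_marginals, simulate_cohort

from .conftest import recovery_config, small_cohort_config


def _rich_panel():
    """Artificial panel with every categorical level represented."""
    from crisisrx.covariates import AGE_GROUPS, CANCER_LEVELS, COUNTRY_GROUPS

    rng = np.random.default_rng(12)
    n = 400
    return pd.DataFrame(
        {
            "individual_id": np.repeat(np.arange(1, n // 2 + 1), 2),
            "month": np.tile([10, 60], n // 2),
            "n_drugs": rng.integers(1, 4, n),
            "ddd": rng.gamma(2.0, 0.5, n),
            "sex": rng.choice(["male", "female"], n),
            "age_group": rng.choice(list(AGE_GROUPS), n),
            "country": np.array(list(COUNTRY_GROUPS))[np.arange(n) % 9],
            "cancer": np.array(list(CANCER_LEVELS))[np.arange(n) % 3],
            "ms": rng.random(n) < 0.3,
            "visits": rng.integers(0, 8, n),
            "family_in_cohort": rng.random(n) < 0.2,
            "unempl_quintile": np.arange(n) % 5 + 1,
            "unempl_lt_quintile": (np.arange(n) + 2) % 5 + 1,
        }
    )


class TestBuildDesign:
    def test_intercept_only(self, small_sim):
        d = build_design(small_sim.panel, ModelSpec(fixed_terms=[]))
        assert d.X.shape[1] == 1
        np.testing.assert_array_equal(d.X[:, 0], 1.0)

    def test_reference_categories(self):
        spec = ModelSpec(fixed_terms=["sex", "age_group", "country", "cancer",
                                      "unempl_quintile", "post2009"])
        d = build_design(_rich_panel(), spec)
        # references never appear as columns
        for ref in ("sex_male", "age_15-34", "country_spain", "cancer_none",
                    "unempl_q1"):
            assert ref not in d.colnames
        assert "sex_female" in d.colnames
        age_cols = [c for c in d.colnames if c.startswith("age_")]
        assert len(age_cols) == 5

    def test_audit_table_block_sizes(self):
        spec = ModelSpec(fixed_terms=["sex", "age_group", "country", "ms",
                                      "cancer", "unempl_quintile",
                                      "unempl_lt_quintile", "visits",
                                      "family_in_cohort", "post2009"])
        d = build_design(_rich_panel(), spec)
        audit = d.audit.set_index("term")["n_columns"]
        assert audit["sex"] == 1
        assert audit["age_group"] == 5
        assert audit["country"] == 8
        assert audit["cancer"] == 2
        assert audit["unempl_quintile"] == 4
        assert audit["unempl_lt_quintile"] == 4
        assert audit["visits"] == 1

    def test_unknown_term_raises(self, small_sim):
        with pytest.raises(DesignError, match="nonexistent"):
            build_design(small_sim.panel, ModelSpec(fixed_terms=["nonexistent"]))

    def test_constant_column_raises_named(self, small_sim):
        panel = small_sim.panel.copy()
        panel["flat"] = 3.0
        with pytest.raises(DesignError, match="flat"):
            build_design(panel, ModelSpec(fixed_terms=["flat"]))


class TestSummarize:
    def test_constant_draws(self):
        out = summarize({"a": np.full(100, 2.5)})
        row = out.iloc[0]
        assert row["mean"] == 2.5 and row["sd"] == 0.0
        assert row["q2.5"] == 2.5 and row["q97.5"] == 2.5

    def test_quantile_oracle_1_to_100(self):
        d = np.arange(1, 101, dtype=float)
        row = summarize({"a": d}).iloc[0]
        assert row["q2.5"] == pytest.approx(3.475)
        assert row["q97.5"] == pytest.approx(97.525)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=500)
        a = summarize({"a": d}).drop(columns="rhat")
        b = summarize({"a": rng.permutation(d)}).drop(columns="rhat")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_draws_raise(self):
        with pytest.raises(ValueError):
            summarize({})
        with pytest.raises(ValueError):
            summarize({"a": np.array([])})


@pytest.fixture(scope="module")
def glm_limit_sim():
    """No random effects in truth: the GLM is the exact model."""
    cfg = small_cohort_config(
        n_individuals=105, seed=9, keep_zero_rows=True,
        covariate_marginals={**_default_marginals(), "control_share": 0.0},
        params_count=ParameterSet(
            "poisson_count", {"const": -0.5, "sex_female": 0.2, "post2009": 0.15},
            0.0, 0.0, 0.0),
        params_ddd=ParameterSet(
            "gaussian_ddd", {"const": 1.0, "sex_female": 0.2, "post2009": 0.15},
            0.0, 0.0, 0.5),
    )
    return simulate_cohort(cfg)


class TestFit:
    def test_intercept_only_gaussian_recovers_sample_mean(self, small_sim):
        spec = ModelSpec(family="gaussian_ddd", fixed_terms=[],
                         random_terms=(), overdispersion=False)
        res = PanelGLMM(small_sim.panel, spec).fit(draws=400, warmup=300, seed=1)
        assert res.params["const"] == pytest.approx(
            small_sim.panel["ddd"].mean(), abs=0.02)

    @pytest.mark.parametrize("family,outcome,smfam", [
        ("poisson_count", "n_drugs", sm.families.Poisson()),
        ("gaussian_ddd", "ddd_sim", sm.families.Gaussian()),
    ])
    def test_zero_random_effect_limit_matches_ml_glm(self, glm_limit_sim,
                                                     family, outcome, smfam):
        """With no random structure the posterior mean equals the MLE."""
        spec = ModelSpec(family=family, fixed_terms=["sex", "post2009"],
                         random_terms=(), overdispersion=False)
        res = PanelGLMM(glm_limit_sim.panel, spec, outcome=outcome).fit(
            draws=1200, warmup=800, seed=4)
        glm = sm.GLM(res.model.design.y, res.model.design.X, family=smfam).fit()
        np.testing.assert_allclose(res.params.to_numpy(), glm.params, atol=0.02)

    def test_null_variance_rw1_shrinks(self, glm_limit_sim):
        """Data with no temporal trend: posterior sigma_alpha stays small."""
        spec = ModelSpec(family="poisson_count", fixed_terms=["sex", "post2009"],
                         overdispersion=False)
        res = PanelGLMM(glm_limit_sim.panel, spec).fit(draws=800, warmup=800, seed=2)
        assert np.percentile(res.draws["sigma_alpha"], 97.5) < 0.1

    def test_single_replicate_recovery_poisson(self):
        cfg = recovery_config(seed=205, n_individuals=200)
        sim = simulate_cohort(cfg)
        spec = ModelSpec(family="poisson_count", fixed_terms=["sex", "post2009"])
        res = PanelGLMM(sim.panel, spec).fit(draws=900, warmup=900, seed=3)
        lo, hi = np.percentile(res.beta_draws("post2009"), [2.5, 97.5])
        assert lo < np.log(1.14) < hi

    def test_exchangeability_monotone_relabel(self, glm_limit_sim):
        """Order-preserving id relabeling leaves the chain untouched."""
        spec = ModelSpec(family="poisson_count", fixed_terms=["sex", "post2009"],
                         random_terms=("iid_intercept",), overdispersion=False)
        panel2 = glm_limit_sim.panel.copy()
        panel2["individual_id"] = panel2["individual_id"] * 10 + 3
        r1 = PanelGLMM(glm_limit_sim.panel, spec).fit(draws=200, warmup=200, seed=5)
        r2 = PanelGLMM(panel2, spec).fit(draws=200, warmup=200, seed=5)
        np.testing.assert_allclose(r1.draws["beta"], r2.draws["beta"])

    def test_by_individual_rw1_smoke(self):
        cfg = small_cohort_config(n_individuals=40, keep_zero_rows=True,
                                  rw1_mode="by_individual")
        sim = simulate_cohort(cfg)
        spec = ModelSpec(family="poisson_count", fixed_terms=["post2009"],
                         rw1_mode="by_individual", overdispersion=False)
        res = PanelGLMM(sim.panel, spec).fit(draws=150, warmup=150, seed=6)
        s = res.summary()
        assert np.isfinite(s["mean"]).all()
        assert res.draws["alpha"].shape[1] == len(res.model.design.months)

    def test_poisson_rejects_negative_outcome(self, small_sim):
        panel = small_sim.panel.copy()
        panel.loc[panel.index[0], "n_drugs"] = -1
        with pytest.raises(DesignError):
            PanelGLMM(panel, ModelSpec(fixed_terms=["post2009"]))


class TestConvergenceGate:
    def test_nonconverged_refuses_rr(self, small_sim):
        spec = ModelSpec(family="gaussian_ddd", fixed_terms=["post2009"],
                         random_terms=(), overdispersion=False)
        model = PanelGLMM(small_sim.panel, spec)
        res = model.fit(draws=100, warmup=50, seed=7)
        # inject a drifting chain: split-Rhat far above threshold
        res.draws["beta"] = np.linspace(0, 5, 100)[:, None] * np.ones(
            (1, res.draws["beta"].shape[1]))
        res._scalar = res._scalar_draws()
        assert not res.converged
        with pytest.raises(NotConvergedError):
            res.relative_risk()
        est = res.relative_risk(force=True)
        assert est.rr > 0
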