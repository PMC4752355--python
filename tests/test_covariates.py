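"""Covariate derivations: MS rule, age groups, unemployment score, quintiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crisisrx.covariates import (
    AGE_GROUPS,
    DegenerateQuintileError,
    age_group,
    assign_quintiles,
    derive_metabolic_syndrome,
    estimate_unemployment_probability,
    hypercholesterolemia,
)


def _clinical_row(htn, dm, obese, tg_high, low_hdl, sex="male"):
    return {
        "hypertension_dx": htn,
        "diabetes_dx": dm,
        "bmi": 31.0 if obese else 25.0,
        "fasting_glucose": 90.0,
        "triglycerides": 160.0 if tg_high else 100.0,
        "hdl": (35.0 if sex == "male" else 45.0) if low_hdl else 60.0,
        "sex": sex,
    }


class TestMetabolicSyndrome:
    def test_all_absent_false(self):
        df = pd.DataFrame([_clinical_row(False, False, False, False, False)])
        assert not derive_metabolic_syndrome(df).iloc[0]

    def test_three_of_five_true(self):
        df = pd.DataFrame([_clinical_row(True, False, True, True, False)])
        assert derive_metabolic_syndrome(df).iloc[0]

    def test_rule_equals_component_count_enumeration(self):
        """All 2^5 presence/absence combinations against the >=3 rule."""
        rows, counts = [], []
        for combo in itertools.product([False, True], repeat=5):
            for sex in ("male", "female"):
                rows.append(_clinical_row(*combo, sex=sex))
                counts.append(sum(combo))
        df = pd.DataFrame(rows)
        got = derive_metabolic_syndrome(df)
        np.testing.assert_array_equal(got.to_numpy(), np.array(counts) >= 3)

    def test_glucose_band_is_101_exclusive_126_inclusive(self):
        base = _clinical_row(True, False, True, False, False)  # 2 components
        for glucose, expected in [(101.0, False), (101.5, True), (126.0, True),
                                  (126.5, False)]:
            row = dict(base, diabetes_dx=False, fasting_glucose=glucose)
            assert derive_metabolic_syndrome(pd.DataFrame([row])).iloc[0] == expected

    def test_hdl_threshold_is_sex_specific(self):
        # HDL 45: low for women (<50), normal for men (>=40)
        for sex, expected in (("female", True), ("male", False)):
            row = dict(_clinical_row(True, False, True, False, False, sex=sex), hdl=45.0)
            assert derive_metabolic_syndrome(pd.DataFrame([row])).iloc[0] == expected

    def test_missing_components_count_as_absent(self):
        df = pd.DataFrame([{"hypertension_dx": True, "sex": "male"}])
        assert not derive_metabolic_syndrome(df).iloc[0]

    def test_sex_required_when_hdl_present(self):
        df = pd.DataFrame([{"hdl": 30.0, "sex": np.nan}])
        with pytest.raises(ValueError, match="sex"):
            derive_metabolic_syndrome(df)

    def test_hypercholesterolemia_not_an_ms_component(self):
        row = dict(_clinical_row(True, False, True, False, False),
                   total_cholesterol=260.0)
        assert not derive_metabolic_syndrome(pd.DataFrame([row])).iloc[0]
        assert hypercholesterolemia([260.0])[0]
        assert not hypercholesterolemia([180.0])[0]


class TestAgeGroup:
    @pytest.mark.parametrize("age,expected", [
        (15, "15-34"), (34.99, "15-34"), (35, "35-44"),
        (44 + 11 / 12, "35-44"), (45, "45-54"), (64.5, "55-64"),
        (74.99, "65-74"), (75, "75+"), (99, "75+"),
    ])
    def test_boundaries(self, age, expected):
        assert age_group(age) == expected

    def test_below_cohort_minimum_flagged(self):
        assert age_group(14.5) == "<15"

    def test_exhaustive_sweep_matches_interval_widths(self):
        ages = np.arange(15, 101)
        got = pd.Series(age_group(ages)).value_counts()
        widths = {"15-34": 20, "35-44": 10, "45-54": 10, "55-64": 10,
                  "65-74": 10, "75+": 26}
        assert dict(got) == widths
        assert list(AGE_GROUPS) == list(widths)


class TestQuintiles:
    def test_sort_based_oracle_1_to_100(self):
        q = assign_quintiles(np.arange(1, 101, dtype=float))
        scores = np.arange(1, 101)
        assert q[scores == 20][0] == 1
        assert q[scores == 21][0] == 2
        # occupancies 20 each
        assert list(np.bincount(q)[1:]) == [20] * 5

    def test_uniform_occupancies(self):
        rng = np.random.default_rng(0)
        q = assign_quintiles(rng.random(10_000))
        counts = np.bincount(q)[1:]
        assert counts.sum() == 10_000
        assert np.all(np.abs(counts - 2000) <= 1)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=500)
        np.testing.assert_array_equal(assign_quintiles(s), assign_quintiles(np.exp(s)))

    def test_degenerate_scores_raise(self):
        with pytest.raises(DegenerateQuintileError):
            assign_quintiles(np.ones(100))


class TestUnemploymentModel:
    def test_labels_independent_of_covariates(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=2000)})
        labels = rng.random(2000) < 0.3
        p = estimate_unemployment_probability(df, labels, ["x"])
        assert abs(p.mean() - labels.mean()) < 0.02

    def test_planted_log_odds_recovered(self):
        """Simulate a strong binary predictor (log-OR = 2) and refit."""
        rng = np.random.default_rng(3)
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        eta = -1.0 + 2.0 * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        df = pd.DataFrame({"x": x})
        p = estimate_unemployment_probability(df, y, ["x"])
        # back out the coefficient from the two fitted probabilities
        p0 = p[x == 0].iloc[0]
        p1 = p[x == 1].iloc[0]
        logit = lambda q: np.log(q / (1 - q))
        est = logit(p1) - logit(p0)
        se = np.sqrt(sum(1 / (len(y[x == g]) * y[x == g].mean() *
                              (1 - y[x == g].mean())) for g in (0, 1)))
        assert abs(est - 2.0) < 1.96 * se * 1.5

    def test_balanced_labels_no_signal(self):
        df = pd.DataFrame({"x": np.zeros(100)})
        labels = np.array([True, False] * 50)
        with np.errstate(all="ignore"):
            p = estimate_unemployment_probability(df, labels, [])
        np.testing.assert_allclose(p, 0.5, atol=1e-6)

    def test_injected_coefficients_used_verbatim(self):
        df = pd.DataFrame({"x": [0.0, 1.0]})
        p = estimate_unemployment_probability(
            df, [np.nan, np.nan], ["x"], coefficients={"const": 0.0, "x": 2.0})
        np.testing.assert_allclose(p, [0.5, 1 / (1 + np.exp(-2.0))])

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=500)})
        y = rng.random(500) < 0.4
        p1 = estimate_unemployment_probability(df, y, ["x"])
        p2 = estimate_unemployment_probability(df, y, ["x"])
        pd.testing.assert_series_equal(p1, p2)
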