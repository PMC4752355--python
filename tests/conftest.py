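import numpy as np
import pandas as pd
import pytest

from crisisrx import ddd as ddd_mod
from crisisrx.synthetic import CohortConfig, ParameterSet, _default_marginals, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return ddd_mod.load_default_registry()


@pytest.fixture(scope="session")
def random_prescriptions(registry):
    """1000 random dispensing records over the 11 study substances."""
    rng = np.random.default_rng(1234)
    n = 1000
    subs = rng.choice(list(registry.table["substance"]), size=n)
    return pd.DataFrame(
        {
            "individual_id": rng.integers(1, 40, n),
            "month": rng.integers(1, 97, n),
            "substance": subs,
            "atc_code": [registry.atc_code(s) for s in subs],
            "n_packs": rng.integers(0, 4, n),
            "units_per_pack": rng.choice([14, 28, 30], n),
            "amount_per_unit_mg": rng.choice([0.5, 1.0, 2.0, 10.0, 20.0], n),
        }
    )


def small_cohort_config(**overrides) -> CohortConfig:
    """Desk-scale defaults shared across tests; keyword overrides win."""
    kw = dict(n_individuals=150, seed=7)
    kw.update(overrides)
    return CohortConfig(**kw)


def recovery_config(seed, family_effects=None, n_individuals=300, **overrides):
    """Simulate-then-fit study conditions: full panel, no forced controls,
    period step of log(1.14), iid intercepts sd 0.3, overdispersion on, and
    zero temporal-trend variance so the step is the sole time signal."""
    truth = float(np.log(1.14))
    marg = {**_default_marginals(), "control_share": 0.0}
    kw = dict(
        n_individuals=n_individuals,
        seed=seed,
        keep_zero_rows=True,
        covariate_marginals=marg,
        params_count=ParameterSet(
            "poisson_count",
            {"const": float(np.log(0.35)), "sex_female": -0.02, "post2009": truth},
            sigma_b=0.3, sigma_alpha=0.0, phi=0.15,
        ),
        params_ddd=ParameterSet(
            "gaussian_ddd",
            {"const": 3.0, "sex_female": 0.05, "post2009": truth},
            sigma_b=0.3, sigma_alpha=0.0, phi=0.5,
        ),
    )
    kw.update(overrides)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def small_sim():
    """One medium synthetic cohort reused by read-only tests."""
    return simulate_cohort(small_cohort_config())
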