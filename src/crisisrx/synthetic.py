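"""Synthetic cohort generator.

Simulates a monthly panel of primary-care users (Jan 2005 - Dec 2012, 96
months) directly from the analysis model with known parameters: individual
demographics with configurable marginals, time-varying clinical and
employment covariates, latent individual intercepts, an RW1 temporal effect,
a configurable post-2009 consumption shift, and dispensing records that
aggregate back to the simulated monthly outcomes exactly.

Every downstream stage of the pipeline (DDD aggregation, covariate
derivation, propensity stratification, model fitting, reporting) is thereby
testable without access to the non-public clinical registry the design
emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariates as cov
from . import ddd as ddd_mod
from .io import CRISIS_MONTH, N_STUDY_MONTHS, STUDY_START_YEAR

__all__ = [
    "ParameterSet",
    "CohortConfig",
    "SimulatedCohort",
    "generate_individuals",
    "simulate_panel",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid cohort configuration (e.g. marginals not summing to 1)."""


@dataclass
class ParameterSet:
    """True parameters for one outcome family.

    ``beta`` maps design-column names to coefficients (log scale for the
    Poisson count family, outcome scale for the Gaussian DDD family).
    ``phi`` is the dispersion scale: the sd of the iid observation-level
    Gaussian effect for ``poisson_count`` (0 disables overdispersion) and the
    residual sd for ``gaussian_ddd``.
    """

    family: str = "poisson_count"
    beta: dict = field(default_factory=dict)
    sigma_b: float = 0.3
    sigma_alpha: float = 0.02
    phi: float = 0.15

    def __post_init__(self):
        if self.family not in ("poisson_count", "gaussian_ddd"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.sigma_b < 0 or self.sigma_alpha < 0:
            raise ConfigError("sigma_b and sigma_alpha must be >= 0")
        if self.phi < 0:
            raise ConfigError("phi must be >= 0")


def _default_marginals() -> dict:
    # country shares renormalized to sum to 1 exactly
    country = {
        "spain": 0.928, "maghreb": 0.024, "latin_america": 0.020, "eu": 0.011,
        "east_europe": 0.007, "india_pakistan": 0.007, "subsaharan_africa": 0.003,
        "other_asia": 0.0, "other_oecd": 0.001,
    }
    s = sum(country.values())
    country = {k: v / s for k, v in country.items()}
    return {
        "female": 0.666,
        "age_mean": 54.37,
        "age_sd": 17.72,
        "country": country,
        "ms_prevalence": 0.016,
        "family_in_cohort": 0.202,
        "control_share": 0.132,  # never consumed psychotropics before 2009
    }


def _default_params_count() -> ParameterSet:
    # intercept chosen so that E[Y | Y >= 1] ~ 1.18 drugs/month among consumers
    return ParameterSet(
        family="poisson_count",
        beta={
            "const": float(np.log(0.35)),
            "sex_female": -0.02,
            "post2009": float(np.log(1.14)),
            "visits": 0.005,
        },
        sigma_b=0.3,
        sigma_alpha=0.02,
        phi=0.15,
    )


def _default_params_ddd() -> ParameterSet:
    # additive DDD-scale effects; monthly DDD among consumers ~ 0.2 with sd ~ 0.5
    return ParameterSet(
        family="gaussian_ddd",
        beta={
            "const": 0.15,
            "sex_female": 0.05,
            "post2009": 0.074,  # = log(1.077), the headline DDD shift magnitude
            "visits": 0.002,
        },
        sigma_b=0.10,
        sigma_alpha=0.01,
        phi=0.45,
    )


@dataclass
class CohortConfig:
    """Study conditions for the generator.

    ``months`` defaults to the 96-month window t = 1..96 (Jan 2005 - Dec
    2012); ``crisis_month`` to t = 49 (Jan 2009).  ``effect_shape`` applies
    the post-2009 coefficient as a step (default) or a linear ramp reaching
    full size at the last month.  ``keep_zero_rows`` keeps non-consuming
    (Y = 0) months in the panel, which simulate-then-fit studies need;
    by default the panel covers consuming months only, as in the source data.
    """

    n_individuals: int = 10_000
    months: np.ndarray = field(default_factory=lambda: np.arange(1, N_STUDY_MONTHS + 1))
    covariate_marginals: dict = field(default_factory=_default_marginals)
    params_count: ParameterSet = field(default_factory=_default_params_count)
    params_ddd: ParameterSet = field(default_factory=_default_params_ddd)
    crisis_month: int = CRISIS_MONTH
    rw1_mode: str = "shared"  # or "by_individual"
    effect_shape: str = "step"  # or "ramp"
    keep_zero_rows: bool = False
    seed: int = 0

    def __post_init__(self):
        self.months = np.asarray(self.months, dtype=int)
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if not np.all(np.diff(self.months) > 0):
            raise ConfigError("months must be strictly increasing")
        if self.rw1_mode not in ("shared", "by_individual"):
            raise ConfigError(f"unknown rw1_mode {self.rw1_mode!r}")
        if self.effect_shape not in ("step", "ramp"):
            raise ConfigError(f"unknown effect_shape {self.effect_shape!r}")
        m = self.covariate_marginals
        for key in ("female", "ms_prevalence", "family_in_cohort", "control_share"):
            if not 0.0 <= m[key] <= 1.0:
                raise ConfigError(f"marginal {key!r}={m[key]} outside [0, 1]")
        csum = sum(m["country"].values())
        if abs(csum - 1.0) > 1e-6 or any(v < 0 for v in m["country"].values()):
            raise ConfigError(f"country marginals must be >= 0 and sum to 1 (got {csum})")


@dataclass
class SimulatedCohort:
    """Everything the generator knows: data tables plus simulation truth."""

    individuals: pd.DataFrame
    panel: pd.DataFrame
    prescriptions: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict
    config: CohortConfig


def generate_individuals(config: CohortConfig) -> pd.DataFrame:
    """One row per individual: demographics and latent baseline states.

    Deterministic given ``config.seed``.  Categorical frequencies follow the
    configured marginals up to binomial noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_individuals
    m = config.covariate_marginals

    sex = np.where(rng.random(n) < m["female"], "female", "male")
    countries = list(m["country"])
    country = rng.choice(countries, size=n, p=[m["country"][c] for c in countries])

    # ages at the study start from a truncated normal on [15, 95]
    age0 = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(m["age_mean"], m["age_sd"], todo.size)
        ok = (draw >= 15.0) & (draw <= 95.0)
        age0[todo[ok]] = draw[ok]
        todo = todo[~ok]
    birth_year = STUDY_START_YEAR - age0
    yr = np.floor(birth_year).astype(int)
    frac = birth_year - yr
    birth_date = pd.to_datetime(
        {"year": yr, "month": np.clip((frac * 12).astype(int) + 1, 1, 12), "day": 1}
    )

    family = rng.random(n) < m["family_in_cohort"]
    pre2009_consumer = rng.random(n) >= m["control_share"]
    ms_latent = rng.random(n) < m["ms_prevalence"]
    neoplasm = rng.random(n) < 0.02
    # individual frailty for the unemployment process
    unempl_frailty = rng.normal(0.0, 0.8, n)

    return pd.DataFrame(
        {
            "individual_id": np.arange(1, n + 1),
            "sex": sex,
            "birth_date": birth_date,
            "country": country,
            "family_in_cohort": family,
            "pre2009_consumer": pre2009_consumer,
            "ms_latent": ms_latent,
            "neoplasm_latent": neoplasm,
            "unempl_frailty": unempl_frailty,
        }
    )


def _rw1_paths(rng, sigma, T, n_paths):
    """Centered (sum-to-zero) RW1 paths with innovation sd ``sigma``."""
    if sigma == 0:
        return np.zeros((n_paths, T))
    steps = rng.normal(0.0, sigma, size=(n_paths, T))
    steps[:, 0] = 0.0
    path = np.cumsum(steps, axis=1)
    return path - path.mean(axis=1, keepdims=True)


def _eta(beta: dict, cols: dict, n_rows: int) -> np.ndarray:
    eta = np.zeros(n_rows)
    for name, b in beta.items():
        if b == 0.0:
            continue
        if name == "const":
            eta += b
        elif name in cols:
            eta += b * cols[name]
        else:
            raise ConfigError(f"beta refers to unknown design column {name!r}")
    return eta


def _design_columns(grid: pd.DataFrame) -> dict:
    """Indicator/numeric columns addressable from ParameterSet.beta."""
    cols = {
        "sex_female": (grid["sex"].to_numpy() == "female").astype(float),
        "ms": grid["ms"].to_numpy().astype(float),
        "visits": grid["visits"].to_numpy().astype(float),
        "family_in_cohort": grid["family_in_cohort"].to_numpy().astype(float),
        "post2009": grid["post2009"].to_numpy().astype(float),
    }
    for g in cov.AGE_GROUPS[1:]:
        cols[f"age_{g}"] = (grid["age_group"].to_numpy() == g).astype(float)
    for g in cov.COUNTRY_GROUPS[1:]:
        cols[f"country_{g}"] = (grid["country"].to_numpy() == g).astype(float)
    for g in cov.CANCER_LEVELS[1:]:
        cols[f"cancer_{g}"] = (grid["cancer"].to_numpy() == g).astype(float)
    for q in range(2, 6):
        cols[f"unempl_q{q}"] = (grid["unempl_quintile"].to_numpy() == q).astype(float)
        cols[f"unempl_lt_q{q}"] = (grid["unempl_lt_quintile"].to_numpy() == q).astype(float)
    return cols


def simulate_panel(
    individuals: pd.DataFrame, config: CohortConfig
) -> SimulatedCohort:
    """Simulate the monthly panel and matching dispensing records.

    For every (individual, month) the linear predictors of both outcome
    families are formed from the evolving covariates, the individual
    intercepts and the RW1 path(s); the drug count is drawn Poisson (with
    optional log-normal overdispersion) and the DDD Gaussian, floored at
    zero.  Dispensing records are then constructed backward from the drawn
    monthly totals so that :func:`crisisrx.ddd.aggregate_monthly` recovers
    the panel's ``n_drugs`` and ``ddd`` columns exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(individuals)
    months = config.months
    T = len(months)
    post = (months >= config.crisis_month).astype(float)
    if config.effect_shape == "ramp":
        ramp = np.zeros(T)
        span = max(int(months.max() - config.crisis_month), 1)
        ramp[post > 0] = (months[post > 0] - config.crisis_month + 1) / (span + 1)
        post = ramp

    # ---- long grid of (individual, month) with evolving covariates --------
    grid = individuals.loc[individuals.index.repeat(T)].reset_index(drop=True)
    grid["month"] = np.tile(months, n)
    grid["post2009"] = np.tile(post, n)

    start = pd.Timestamp(year=STUDY_START_YEAR, month=1, day=1)
    month_start = start + pd.to_timedelta((grid["month"] - 1) * 30.4375, unit="D")
    age = (month_start - grid["birth_date"]).dt.days / 365.25
    grid["age"] = age
    grid["age_group"] = cov.age_group(age.to_numpy())

    grid["visits"] = rng.poisson(2.25, size=len(grid))

    # clinical components consistent with the latent MS flag
    ms = grid["ms_latent"].to_numpy()
    grid["hypertension_dx"] = ms | (rng.random(len(grid)) < 0.10)
    grid["diabetes_dx"] = rng.random(len(grid)) < 0.03
    grid["bmi"] = np.where(ms, 32.0, 26.0) + rng.normal(0, 1.5, len(grid))
    grid["fasting_glucose"] = rng.normal(92, 8, len(grid))
    grid["hdl"] = rng.normal(55, 8, len(grid))
    grid["triglycerides"] = np.where(ms, 170.0, 110.0) + rng.normal(0, 15, len(grid))
    grid["total_cholesterol"] = rng.normal(190, 30, len(grid))
    grid["ms"] = cov.derive_metabolic_syndrome(
        grid[["hypertension_dx", "diabetes_dx", "bmi", "fasting_glucose", "triglycerides", "hdl"]],
        sex=grid["sex"],
    ).to_numpy()

    neo = grid["neoplasm_latent"].to_numpy()
    fear = (~neo) & (rng.random(len(grid)) < 0.01)
    grid["cancer"] = np.where(neo, "neoplasm", np.where(fear, "fear_of_cancer", "none"))

    # unemployment: logistic in age/country/frailty with a post-crisis surge
    young = (age.to_numpy() < 35).astype(float)
    foreign = (grid["country"].to_numpy() != "spain").astype(float)
    lin = (
        -2.2
        + 0.6 * young
        + 0.5 * foreign
        + 1.0 * grid["post2009"].to_numpy()
        + grid["unempl_frailty"].to_numpy()
    )
    p_unempl = 1.0 / (1.0 + np.exp(-lin))
    p_lt = 1.0 / (1.0 + np.exp(-(lin - 1.0)))
    grid["p_unemployed_true"] = p_unempl
    grid["p_long_term_true"] = p_lt
    grid["unemployed"] = rng.random(len(grid)) < p_unempl
    grid["unempl_quintile"] = cov.assign_quintiles(p_unempl)
    grid["unempl_lt_quintile"] = cov.assign_quintiles(p_lt)

    # ---- latent structure and outcomes ------------------------------------
    pc, pd_ = config.params_count, config.params_ddd
    cols = _design_columns(grid)
    i_idx = np.repeat(np.arange(n), T)
    t_idx = np.tile(np.arange(T), n)

    truth = {}
    y = {}
    for tag, ps in (("count", pc), ("ddd", pd_)):
        b = rng.normal(0.0, ps.sigma_b, n) if ps.sigma_b > 0 else np.zeros(n)
        n_paths = n if config.rw1_mode == "by_individual" else 1
        alpha = _rw1_paths(rng, ps.sigma_alpha, T, n_paths)
        a_of_row = alpha[i_idx % n_paths, t_idx]
        eta = _eta(ps.beta, cols, len(grid)) + b[i_idx] + a_of_row
        if tag == "count":
            e = rng.normal(0.0, ps.phi, len(grid)) if ps.phi > 0 else 0.0
            y[tag] = rng.poisson(np.exp(eta + e))
        else:
            y[tag] = np.maximum(rng.normal(eta, ps.phi), 0.0)
        truth[tag] = {"b": b, "alpha": alpha, "params": ps}

    # at most the 11 study substances can be distinct within a month
    grid["n_drugs"] = np.minimum(y["count"], 11)
    # raw Gaussian-family draw, kept alongside the realized (dispensed) DDD
    grid["ddd_sim"] = y["ddd"]
    grid["ddd_target"] = y["ddd"]

    # controls never consume before the crisis
    control = ~grid["pre2009_consumer"].to_numpy()
    pre = grid["month"].to_numpy() < config.crisis_month
    grid.loc[control & pre, "n_drugs"] = 0

    keep = grid if config.keep_zero_rows else grid[grid["n_drugs"] >= 1]
    panel = keep.drop(
        columns=["ms_latent", "neoplasm_latent", "unempl_frailty", "birth_date"]
    ).reset_index(drop=True)

    prescriptions = _emit_prescriptions(panel, rng)
    # define the panel DDD as the exact aggregate of the emitted records
    agg = ddd_mod.aggregate_monthly(prescriptions)
    panel = panel.drop(columns=["ddd_target"]).merge(
        agg.rename(columns={"n_drugs": "n_drugs_check"}), on=["individual_id", "month"], how="left"
    )
    panel["ddd"] = panel["ddd"].fillna(0.0)
    if "n_drugs_check" in panel:
        mism = panel["n_drugs_check"].fillna(0).astype(int) != panel["n_drugs"]
        if mism.any():
            raise AssertionError("prescription back-construction broke the drug count")
        panel = panel.drop(columns=["n_drugs_check"])

    clinical = grid[
        [
            "individual_id", "month", "hypertension_dx", "diabetes_dx", "bmi",
            "fasting_glucose", "hdl", "triglycerides", "total_cholesterol",
            "visits", "cancer", "unemployed",
        ]
    ].reset_index(drop=True)

    return SimulatedCohort(
        individuals=individuals,
        panel=panel,
        prescriptions=prescriptions,
        clinical=clinical,
        truth=truth,
        config=config,
    )


def _emit_prescriptions(panel: pd.DataFrame, rng) -> pd.DataFrame:
    """Back-construct dispensing events matching monthly totals exactly.

    Each consuming month gets ``n_drugs`` distinct substances chosen
    uniformly from the 11 study drugs; the month's DDD total is split across
    them with Dirichlet weights and realized as one record per substance
    (one pack of 28 units whose per-unit amount hits the target DDD).
    """
    registry = ddd_mod.load_default_registry()
    rows = panel[panel["n_drugs"] >= 1]
    if rows.empty:
        return pd.DataFrame(
            columns=["individual_id", "month", "substance", "atc_code",
                     "n_packs", "units_per_pack", "amount_per_unit_mg", "drug_class"]
        )
    substances = np.array(ddd_mod.ANXIOLYTICS + ddd_mod.ANTIDEPRESSANTS)
    counts = rows["n_drugs"].to_numpy()
    total = int(counts.sum())
    sub_idx = np.empty(total, dtype=int)
    shares = np.empty(total)
    pos = 0
    n_subs = len(substances)
    for c in counts:
        if c == 1:
            sub_idx[pos] = rng.integers(n_subs)
            shares[pos] = 1.0
        else:
            sub_idx[pos : pos + c] = rng.choice(n_subs, size=c, replace=False)
            shares[pos : pos + c] = rng.dirichlet(np.ones(c))
        pos += c
    rep = np.repeat(np.arange(len(rows)), counts)
    ddd_target = np.maximum(rows["ddd_target"].to_numpy(), 1e-6)[rep] * shares
    subs = substances[sub_idx]
    ddd_amounts = np.array([registry.ddd_amount(s) for s in substances])[sub_idx]
    units = 28
    amount = ddd_target * ddd_amounts / units
    out = pd.DataFrame(
        {
            "individual_id": rows["individual_id"].to_numpy()[rep],
            "month": rows["month"].to_numpy()[rep],
            "substance": subs,
            "atc_code": [registry.atc_code(s) for s in subs],
            "n_packs": 1,
            "units_per_pack": units,
            "amount_per_unit_mg": amount,
            "drug_class": [ddd_mod.classify(s) for s in subs],
        }
    )
    return out.reset_index(drop=True)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Convenience: :func:`generate_individuals` + :func:`simulate_panel`."""
    return simulate_panel(generate_individuals(config), config)
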