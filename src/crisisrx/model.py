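"""Bayesian random-coefficient panel GLMM for monthly drug consumption.

The observation model for individual i in month t is

    E(Y_it) = mu_it,    g(mu_it) = eta_it,
    eta_it  = beta_0 + x_it' beta + b_i + alpha_t(i) [+ e_it]

with g = log and Y Poisson for the drug count (overdispersion realized as
iid Gaussian observation-level effects e_it), and g = identity, Y Gaussian
with constant residual variance for the DDD.  b_i ~ N(0, sigma_b^2) are iid
individual intercepts; alpha is a first-order random walk over the 96 study
months (shared path by default, optionally one path per individual), carried
with a sum-to-zero constraint so the fixed intercept stays identified.

Inference is MCMC (see :mod:`crisisrx._mcmc`) under weakly-informative
priors: Normal(0, beta_sd^2) on fixed effects and half-Normal(0, sd_scale)
on all standard deviations.  The usage mirrors statsmodels::

    model = PanelGLMM(panel, ModelSpec(family="poisson_count",
                                       fixed_terms=["sex", "post2009"]))
    res = model.fit(draws=1000, warmup=1000, seed=7)
    res.summary()
    res.relative_risk()          # exp(post-2009 contrast) with 95% CrI
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import covariates as cov
from ._mcmc import run_gaussian, run_poisson
from .io import CRISIS_MONTH

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "Design",
    "build_design",
    "PanelGLMM",
    "PanelGLMMResults",
    "summarize",
    "DesignError",
    "NotConvergedError",
]


class DesignError(ValueError):
    """The panel cannot support the requested design."""


class NotConvergedError(RuntimeError):
    """Posterior draws failed the convergence check and --force is not set."""


@dataclass
class PriorSpec:
    """Weakly-informative defaults: N(0, 5^2) betas, half-N(0, 1) sds."""

    beta_sd: float = 5.0
    sd_scale: float = 1.0


@dataclass
class ModelSpec:
    """What to fit: family, fixed terms, random structure, priors."""

    family: str = "poisson_count"
    fixed_terms: list = field(default_factory=lambda: ["sex", "post2009"])
    random_terms: tuple = ("iid_intercept", "rw1_time")
    rw1_mode: str = "shared"  # or "by_individual"
    overdispersion: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)
    crisis_month: int = CRISIS_MONTH

    def __post_init__(self):
        if self.family not in ("poisson_count", "gaussian_ddd"):
            raise DesignError(f"unknown family {self.family!r}")
        if self.rw1_mode not in ("shared", "by_individual"):
            raise DesignError(f"unknown rw1_mode {self.rw1_mode!r}")


# term name -> (panel column, expansion) ------------------------------------
# categorical terms expand to indicators with the printed reference category
_CATEGORICAL = {
    "sex": ("sex", ["male", "female"], "sex_{}"),          # reference: men
    "age_group": ("age_group", list(cov.AGE_GROUPS), "age_{}"),
    "country": ("country", list(cov.COUNTRY_GROUPS), "country_{}"),
    "cancer": ("cancer", list(cov.CANCER_LEVELS), "cancer_{}"),
    "unempl_quintile": ("unempl_quintile", [1, 2, 3, 4, 5], "unempl_q{}"),
    "unempl_lt_quintile": ("unempl_lt_quintile", [1, 2, 3, 4, 5], "unempl_lt_q{}"),
    "stratum": ("stratum", None, "stratum_{}"),            # levels from data
}
_NUMERIC = {
    "ms": "ms",
    "visits": "visits",
    "family_in_cohort": "family_in_cohort",
    "post2009": "post2009",
}

#: the full printed predictor (plus the family-in-cohort adjustment)
FULL_TERMS = [
    "sex", "age_group", "country", "ms", "cancer",
    "unempl_quintile", "unempl_lt_quintile", "visits", "family_in_cohort",
    "post2009",
]


@dataclass
class Design:
    """Numeric design plus index maps and a term -> column audit table."""

    X: np.ndarray
    colnames: list
    ind_codes: np.ndarray
    ind_ids: np.ndarray
    t_codes: np.ndarray
    months: np.ndarray
    y: np.ndarray
    audit: pd.DataFrame
    const_ix: int
    post_col_ix: int | None


def build_design(panel: pd.DataFrame, spec: ModelSpec, outcome: str | None = None) -> Design:
    """Expand the spec's terms into a dense design matrix.

    Reference categories follow the study conventions: men, 15-34 years,
    Spain, cancer=none, first quintile, first stratum.  Raises
    :class:`DesignError` naming any unknown term or all-constant column.
    """
    if outcome is None:
        outcome = "n_drugs" if spec.family == "poisson_count" else "ddd"
    if outcome not in panel.columns:
        raise DesignError(f"panel lacks outcome column {outcome!r}")

    work = panel
    if "post2009" in spec.fixed_terms and "post2009" not in work.columns:
        work = work.copy()
        work["post2009"] = (work["month"] >= spec.crisis_month).astype(float)

    cols: list[np.ndarray] = [np.ones(len(work))]
    names: list[str] = ["const"]
    audit_rows = [{"term": "const", "n_columns": 1, "reference": "", "columns": "const"}]

    for term in spec.fixed_terms:
        if term in _CATEGORICAL:
            src, levels, fmt = _CATEGORICAL[term]
            if src not in work.columns:
                raise DesignError(f"panel lacks column {src!r} for term {term!r}")
            vals = work[src]
            if levels is None:
                levels = sorted(vals.unique())
            new = []
            for lev in levels[1:]:
                names.append(fmt.format(lev))
                cols.append((vals == lev).to_numpy(dtype=float))
                new.append(names[-1])
            audit_rows.append(
                {"term": term, "n_columns": len(new), "reference": str(levels[0]),
                 "columns": ",".join(new)}
            )
        elif term in _NUMERIC:
            src = _NUMERIC[term]
            if src not in work.columns:
                raise DesignError(f"panel lacks column {src!r} for term {term!r}")
            names.append(src)
            cols.append(work[src].to_numpy(dtype=float))
            audit_rows.append({"term": term, "n_columns": 1, "reference": "", "columns": src})
        elif term in work.columns:  # ad-hoc numeric column (e.g. interactions)
            names.append(term)
            cols.append(work[term].to_numpy(dtype=float))
            audit_rows.append({"term": term, "n_columns": 1, "reference": "", "columns": term})
        else:
            raise DesignError(f"unknown design term {term!r}")

    X = np.column_stack(cols)
    for j, name in enumerate(names):
        if name != "const" and np.ptp(X[:, j]) == 0.0:
            raise DesignError(f"design column {name!r} is constant (rank deficiency)")

    ind_ids, ind_codes = np.unique(work["individual_id"].to_numpy(), return_inverse=True)
    months, t_codes = np.unique(work["month"].to_numpy(), return_inverse=True)
    if "rw1_time" in spec.random_terms and len(months) < 2:
        raise DesignError("RW1 time effect requires at least 2 months")

    return Design(
        X=X,
        colnames=names,
        ind_codes=ind_codes,
        ind_ids=ind_ids,
        t_codes=t_codes,
        months=months,
        y=work[outcome].to_numpy(dtype=float),
        audit=pd.DataFrame(audit_rows),
        const_ix=0,
        post_col_ix=names.index("post2009") if "post2009" in names else None,
    )


def summarize(draws: dict, param_order: list | None = None) -> pd.DataFrame:
    """Posterior means, sds and central 95% intervals for scalar parameters.

    ``draws`` maps parameter names to 1-D arrays of equal length.  Quantiles
    use linear interpolation.  Ordering is the given order (stable).
    """
    if not draws:
        raise ValueError("no posterior draws to summarize")
    names = param_order if param_order is not None else list(draws)
    rows = []
    for name in names:
        d = np.asarray(draws[name], dtype=float).ravel()
        if d.size == 0:
            raise ValueError(f"empty draws for parameter {name!r}")
        rows.append(
            {
                "parameter": name,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=0)),
                "q2.5": float(np.percentile(d, 2.5)),
                "q97.5": float(np.percentile(d, 97.5)),
                "rhat": _split_rhat(d),
            }
        )
    return pd.DataFrame(rows)


def _split_rhat(d: np.ndarray) -> float:
    d = np.asarray(d, dtype=float).ravel()
    if d.size < 4 or np.ptp(d) == 0.0:
        return 1.0
    half = d.size // 2
    arr = np.stack([d[:half], d[half : 2 * half]])
    r = float(az.rhat(arr.reshape(2, half)))
    return r if np.isfinite(r) else 1.0


class PanelGLMM:
    """Random-coefficient panel GLMM bound to a consumption panel.

    Parameters
    ----------
    panel : DataFrame with one row per (individual, month) and the outcome
        and covariate columns the spec's terms require.
    spec : ModelSpec.
    outcome : override the family's default outcome column.
    """

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec, outcome: str | None = None):
        self.spec = spec
        self.panel = panel
        self.design = build_design(panel, spec, outcome=outcome)
        if spec.family == "poisson_count" and np.any(self.design.y < 0):
            raise DesignError("Poisson outcome has negative values")

    @classmethod
    def from_dataframe(cls, panel, family="poisson_count", fixed_terms=None, **kw):
        spec = ModelSpec(
            family=family,
            fixed_terms=list(fixed_terms) if fixed_terms is not None else ["sex", "post2009"],
            **kw,
        )
        return cls(panel, spec)

    # -- internal ----------------------------------------------------------
    def _sampler_data(self) -> dict:
        d = self.design
        # columns constant within individuals ride a ridge with the iid
        # intercepts; the samplers give them eta-invariant translation moves
        ind_const = []
        if "iid_intercept" in self.spec.random_terms:
            counts = np.bincount(d.ind_codes).astype(float)
            for j in range(d.X.shape[1]):
                if j == d.const_ix:
                    continue
                v = d.X[:, j]
                mean_i = np.bincount(d.ind_codes, weights=v) / counts
                if np.max(np.abs(v - mean_i[d.ind_codes])) == 0.0:
                    ind_const.append((j, mean_i))
        return {
            "ind_const": ind_const,
            "X": d.X,
            "y": d.y,
            "ind": d.ind_codes,
            "tt": d.t_codes,
            "n_ind": len(d.ind_ids),
            "T": len(d.months),
            "has_iid": "iid_intercept" in self.spec.random_terms,
            "has_rw1": "rw1_time" in self.spec.random_terms,
            "has_overdispersion": bool(self.spec.overdispersion),
            "rw1_by_individual": self.spec.rw1_mode == "by_individual",
            "const_ix": d.const_ix,
        }

    def _ml_start(self):
        """IRLS GLM fit for the starting point and beta proposal covariance."""
        d = self.design
        fam = sm.families.Poisson() if self.spec.family == "poisson_count" else sm.families.Gaussian()
        try:
            res = sm.GLM(d.y, d.X, family=fam).fit()
            chol = np.linalg.cholesky(res.cov_params() + 1e-10 * np.eye(d.X.shape[1]))
            return np.asarray(res.params), (2.4 / np.sqrt(d.X.shape[1])) * chol
        except Exception:
            p = d.X.shape[1]
            return np.zeros(p), 0.02 * np.eye(p)

    def fit(
        self,
        draws: int = 1000,
        warmup: int = 1000,
        thin: int = 1,
        chains: int = 1,
        seed: int = 0,
    ) -> "PanelGLMMResults":
        """Run the MCMC and return a results object with stacked draws."""
        data = self._sampler_data()
        start, prop_chol = self._ml_start()
        has_rw1 = data["has_rw1"]
        translate_col = self.design.post_col_ix if has_rw1 else None
        post_mask = (self.design.months >= self.spec.crisis_month) if has_rw1 else None

        chain_draws = []
        ss = np.random.SeedSequence([int(seed) % (2**31), 17])
        for child in ss.spawn(chains):
            rng = np.random.default_rng(child)
            n_iter = warmup + draws * thin
            if self.spec.family == "poisson_count":
                out = run_poisson(
                    data, self.spec.priors, n_iter, warmup, thin, rng,
                    start=start, prop_chol=prop_chol,
                    translate_col=translate_col, translate_post_mask=post_mask,
                )
            else:
                out = run_gaussian(
                    data, self.spec.priors, n_iter, warmup, thin, rng,
                    start=start,
                    translate_col=translate_col, translate_post_mask=post_mask,
                )
            chain_draws.append(out)

        stacked = {
            k: np.concatenate([c[k] for c in chain_draws], axis=0) for k in chain_draws[0]
        }
        return PanelGLMMResults(self, stacked, n_chains=chains)


class PanelGLMMResults:
    """Posterior draws plus the estimates/uncertainty/diagnostics surface."""

    def __init__(self, model: PanelGLMM, draws: dict, n_chains: int = 1):
        self.model = model
        self.draws = draws
        self.n_chains = n_chains
        self._scalar = self._scalar_draws()

    def _scalar_draws(self) -> dict:
        d = {}
        for j, name in enumerate(self.model.design.colnames):
            d[f"beta[{name}]"] = self.draws["beta"][:, j]
        for k in ("sigma", "sigma_b", "sigma_alpha", "sigma_e"):
            if k in self.draws:
                d[k] = self.draws[k]
        return d

    @property
    def params(self) -> pd.Series:
        """Posterior means of the fixed effects, indexed by column name."""
        return pd.Series(
            self.draws["beta"].mean(axis=0), index=self.model.design.colnames
        )

    def beta_draws(self, name: str) -> np.ndarray:
        try:
            j = self.model.design.colnames.index(name)
        except ValueError:
            raise KeyError(f"unknown fixed-effect column {name!r}") from None
        return self.draws["beta"][:, j]

    def summary(self) -> pd.DataFrame:
        """PosteriorSummary table: mean, sd, 2.5/97.5 percentiles, rhat."""
        return summarize(self._scalar, list(self._scalar))

    @property
    def max_rhat(self) -> float:
        return float(self.summary()["rhat"].max())

    @property
    def converged(self) -> bool:
        return self.max_rhat < 1.1

    def check_converged(self, force: bool = False):
        if not self.converged and not force:
            raise NotConvergedError(
                f"max split-Rhat {self.max_rhat:.3f} >= 1.1; rerun longer or pass force=True"
            )

    # rr_analysis surface ---------------------------------------------------
    def relative_risk(self, contrast=None, force: bool = False):
        from .rr import relative_risk

        return relative_risk(self, contrast=contrast, force=force)

    def monthly_rr_path(self, reference="pre_mean", force: bool = False):
        from .rr import monthly_rr_path

        return monthly_rr_path(self, reference=reference, force=force)
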