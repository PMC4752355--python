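"""Relative risks of post-crisis consumption from posterior draws.

The headline quantity is the relative risk of the 2009-2012 period versus
2005-2008: the antilog of the period contrast, summarized by its posterior
median and central 95% credibility interval.  An estimate is flagged
significant exactly when that interval does not contain 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec, PanelGLMM, PanelGLMMResults

__all__ = [
    "RelativeRiskEstimate",
    "relative_risk",
    "subgroup_table",
    "monthly_rr_path",
]


@dataclass
class RelativeRiskEstimate:
    """Posterior summary of exp(contrast) with the interval-based flag."""

    subgroup: str
    outcome: str
    rr: float
    ci_low: float
    ci_high: float
    significant: bool
    n: int = 0

    @classmethod
    def from_draws(cls, contrast_draws, subgroup="all", outcome="all", n=0):
        ex = np.exp(np.asarray(contrast_draws, dtype=float))
        lo, hi = np.percentile(ex, [2.5, 97.5])
        return cls(
            subgroup=str(subgroup),
            outcome=str(outcome),
            rr=float(np.median(ex)),
            ci_low=float(lo),
            ci_high=float(hi),
            significant=not (lo <= 1.0 <= hi),
            n=int(n),
        )


def relative_risk(
    results: PanelGLMMResults, contrast=None, subgroup="all", outcome="all", force=False
) -> RelativeRiskEstimate:
    """Antilog of a linear contrast of fixed effects.

    ``contrast`` maps design-column names to weights; the default is the
    post-2009 period indicator alone.
    """
    results.check_converged(force=force)
    if contrast is None:
        contrast = {"post2009": 1.0}
    acc = np.zeros(results.draws["beta"].shape[0])
    for name, w in contrast.items():
        acc = acc + w * results.beta_draws(name)
    return RelativeRiskEstimate.from_draws(
        acc, subgroup=subgroup, outcome=outcome, n=len(results.model.design.y)
    )


def subgroup_table(
    panel: pd.DataFrame,
    spec: ModelSpec,
    subgroups: dict[str, str] | list[str],
    outcome_label: str = "all",
    fit_kwargs: dict | None = None,
    force: bool = False,
) -> pd.DataFrame:
    """Period RRs within subgroups via period-by-subgroup interactions.

    For each stratifier (a panel column), the model is refit replacing the
    global period indicator with one period indicator per level, yielding a
    per-level post-2009 contrast from a single model.  Empty levels are
    flagged with NaN estimates, never silently omitted.
    """
    fit_kwargs = dict(fit_kwargs or {})
    if isinstance(subgroups, dict):
        items = list(subgroups.items())
    else:
        items = [(s, s) for s in subgroups]
    rows = []
    for label, column in items:
        if column not in panel.columns:
            raise KeyError(f"subgroup column {column!r} not in panel")
        work = panel.copy()
        post = (work["month"] >= spec.crisis_month).astype(float)
        levels = sorted(work[column].dropna().unique(), key=str)
        inter_cols = []
        empty_levels = []
        for lev in levels:
            n_post = int(((work[column] == lev) & (post > 0)).sum())
            if n_post == 0:
                # no post-period observations: the contrast is undefined;
                # flag the row instead of adding an all-zero column
                empty_levels.append(lev)
                continue
            cname = f"post2009_x_{column}_{lev}"
            work[cname] = post * (work[column] == lev).astype(float)
            inter_cols.append((lev, cname))
        for lev in empty_levels:
            rows.append(
                {"stratifier": label, "level": str(lev), "outcome": outcome_label,
                 "rr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "significant": False, "n": 0, "empty": True}
            )
        if not inter_cols:
            continue
        fixed = [t for t in spec.fixed_terms if t != "post2009"] + [c for _, c in inter_cols]
        sub_spec = ModelSpec(
            family=spec.family,
            fixed_terms=fixed,
            random_terms=spec.random_terms,
            rw1_mode=spec.rw1_mode,
            overdispersion=spec.overdispersion,
            priors=spec.priors,
            crisis_month=spec.crisis_month,
        )
        res = PanelGLMM(work, sub_spec).fit(**fit_kwargs)
        res.check_converged(force=force)
        for lev, cname in inter_cols:
            n_lev = int(((work[column] == lev) & (post > 0)).sum())
            est = RelativeRiskEstimate.from_draws(
                res.beta_draws(cname), subgroup=f"{label}={lev}", outcome=outcome_label, n=n_lev
            )
            rows.append(
                {"stratifier": label, "level": str(lev), "outcome": outcome_label,
                 "rr": est.rr, "ci_low": est.ci_low, "ci_high": est.ci_high,
                 "significant": est.significant, "n": est.n, "empty": False}
            )
    return pd.DataFrame(rows)


def monthly_rr_path(results: PanelGLMMResults, reference="pre_mean", force=False) -> pd.DataFrame:
    """Per-month relative risk of the fitted time profile with 95% bands.

    The profile combines the RW1 path with the period step (when present);
    each draw is referenced to its pre-crisis mean level (default) or to a
    single reference month, then antilogged.
    """
    results.check_converged(force=force)
    if "alpha" not in results.draws:
        raise ValueError("model has no RW1 time effect; monthly path undefined")
    months = results.model.design.months
    crisis = results.model.spec.crisis_month
    profile = results.draws["alpha"].copy()
    if results.model.design.post_col_ix is not None:
        step = results.beta_draws("post2009")
        profile = profile + np.outer(step, (months >= crisis).astype(float))
    if reference == "pre_mean":
        pre = months < crisis
        if not pre.any():
            raise ValueError("no pre-crisis months to reference against")
        ref = profile[:, pre].mean(axis=1, keepdims=True)
    else:
        j = int(np.where(months == int(reference))[0][0])
        ref = profile[:, [j]]
    rr = np.exp(profile - ref)
    lo, med, hi = np.percentile(rr, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {"month": months, "rr": med, "ci_low": lo, "ci_high": hi,
         "significant": ~((lo <= 1.0) & (1.0 <= hi))}
    )
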