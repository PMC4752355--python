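"""Propensity-score counterfactual construction.

The natural-experiment design needs a comparison group: individuals who had
not consumed any psychotropic drug before the 2009 crisis onset (controls)
versus prior consumers (cases).  Exact matching on the full covariate set is
impractical, so group membership is modelled by logistic regression on the
same conditioning variables as the outcome model's linear predictor; the
predicted probability (the propensity score) then drives nearest-neighbour
matching (sensitivity path) and quantile stratification (primary
adjustment, entering the panel model as a fixed factor).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "label_case_control",
    "estimate_propensity",
    "match",
    "stratify",
    "standardized_mean_differences",
    "balance_report",
]


def label_case_control(
    panel: pd.DataFrame, crisis_month: int, individuals: pd.DataFrame | None = None
) -> pd.Series:
    """Case flag per individual: any consumption in any month before the crisis.

    ``panel`` holds consuming months only, so an individual is a case iff
    they appear in a pre-crisis row.  Pass ``individuals`` to label the full
    cohort including never-consumers (otherwise only panel individuals are
    labelled).
    """
    if not (panel["month"] < crisis_month).any():
        raise ValueError("panel has no months before the crisis onset")
    consumed_pre = set(panel.loc[panel["month"] < crisis_month, "individual_id"])
    ids = (
        individuals["individual_id"]
        if individuals is not None
        else pd.Series(sorted(panel["individual_id"].unique()), name="individual_id")
    )
    flags = ids.isin(consumed_pre)
    flags.index = ids.to_numpy()
    flags.name = "case"
    return flags


def estimate_propensity(
    data: pd.DataFrame, case_flag, covariate_cols: list[str]
) -> pd.Series:
    """Logistic propensity of being a pre-crisis consumer; deterministic."""
    X = sm.add_constant(data[covariate_cols].astype(float), has_constant="add")
    y = pd.Series(case_flag, index=data.index).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        p = np.asarray(res.predict(X))
    except Exception:
        logger.warning("propensity logistic fit unstable; using L2-penalized fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0, maxiter=500)
        eta = X.to_numpy() @ np.asarray(res.params)
        p = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(p, index=data.index, name="propensity")


def match(
    propensity, case_flag, ratio: int = 1, caliper: float | None = None
) -> pd.DataFrame:
    """Greedy nearest-neighbour matching of cases to controls, with replacement.

    ``caliper`` defaults to 0.2 x sd of the logit propensity; a case with no
    control inside the caliper is reported with ``matched = False`` rather
    than dropped silently.  Returns one row per case-control pairing plus
    one row per unmatched case (control_id = NaN).
    """
    p = pd.Series(propensity).astype(float)
    c = pd.Series(case_flag).astype(bool)
    if not (~c).any():
        raise ValueError("matching needs at least one control")
    eps = 1e-12
    logit = np.log((p + eps) / (1 - p + eps))
    if caliper is None:
        caliper = 0.2 * float(logit.std(ddof=1))
    ctrl_ids = p.index[~c].to_numpy()
    ctrl_p = p[~c].to_numpy()
    order = np.argsort(ctrl_p, kind="stable")
    ctrl_ids, ctrl_p = ctrl_ids[order], ctrl_p[order]

    rows = []
    set_id = 0
    for case_id in p.index[c]:
        set_id += 1
        target = p[case_id]
        j = np.searchsorted(ctrl_p, target)
        cand = [k for k in (j - 1, j) if 0 <= k < len(ctrl_p)]
        # expand outward to collect `ratio` nearest controls
        picked = []
        left = min(cand) if cand else 0
        right = max(cand) if cand else -1
        seen = set()
        while len(picked) < ratio:
            best_k, best_d = None, np.inf
            for k in (left, right):
                if 0 <= k < len(ctrl_p) and k not in seen:
                    d = abs(ctrl_p[k] - target)
                    if d < best_d:
                        best_k, best_d = k, d
            if best_k is None:
                break
            seen.add(best_k)
            if best_d <= caliper:
                picked.append((ctrl_ids[best_k], best_d))
            if best_k == left:
                left -= 1
            else:
                right += 1
        if picked:
            for ctrl, dist in picked:
                rows.append(
                    {"matched_set_id": set_id, "case_id": case_id, "control_id": ctrl,
                     "distance": dist, "matched": True}
                )
        else:
            rows.append(
                {"matched_set_id": set_id, "case_id": case_id, "control_id": np.nan,
                 "distance": np.nan, "matched": False}
            )
    out = pd.DataFrame(rows)
    n_un = int((~out["matched"]).sum()) if len(out) else 0
    if n_un:
        logger.warning("match: %d case(s) unmatched within caliper %.4g", n_un, caliper)
    return out


def stratify(propensity, n_strata: int = 5, case_flag=None) -> pd.Series:
    """Quantile strata (1..n_strata) on the pooled propensity distribution.

    Warns, naming the stratum, if any stratum lacks cases or controls.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    p = pd.Series(propensity).astype(float)
    if n_strata == 1:
        out = pd.Series(1, index=p.index, name="stratum")
    else:
        qs = np.quantile(p, np.linspace(0, 1, n_strata + 1)[1:-1])
        out = pd.Series(
            np.searchsorted(qs, p.to_numpy(), side="left") + 1, index=p.index, name="stratum"
        )
    if case_flag is not None:
        c = pd.Series(case_flag).astype(bool)
        for s in range(1, n_strata + 1):
            in_s = out == s
            if in_s.any() and (not c[in_s].any() or not (~c[in_s]).any()):
                logger.warning("stratify: stratum %d has zero cases or zero controls", s)
    return out


def standardized_mean_differences(
    data: pd.DataFrame, case_flag, covariate_cols: list[str], strata=None
) -> pd.DataFrame:
    """Case-control SMD per covariate, optionally within propensity strata.

    With ``strata``, per-stratum SMDs are combined as a stratum-size weighted
    mean of absolute values — the balance measure the stratification is meant
    to shrink.
    """
    c = pd.Series(case_flag, index=data.index).astype(bool)

    def smd(frame, flags):
        res = {}
        for col in covariate_cols:
            x1 = frame.loc[flags, col].astype(float)
            x0 = frame.loc[~flags, col].astype(float)
            if len(x1) < 2 or len(x0) < 2:
                res[col] = np.nan
                continue
            sp = np.sqrt((x1.var(ddof=1) + x0.var(ddof=1)) / 2)
            res[col] = 0.0 if sp == 0 else (x1.mean() - x0.mean()) / sp
        return res

    rows = {"covariate": covariate_cols, "smd_crude": [smd(data, c)[k] for k in covariate_cols]}
    if strata is not None:
        s = pd.Series(strata, index=data.index)
        weighted = np.zeros(len(covariate_cols))
        wsum = 0.0
        for lev in sorted(s.unique()):
            in_s = s == lev
            if c[in_s].nunique() < 2:
                continue
            vals = smd(data[in_s], c[in_s])
            w = float(in_s.sum())
            weighted += w * np.abs([vals[k] if np.isfinite(vals[k]) else 0.0 for k in covariate_cols])
            wsum += w
        rows["smd_stratified"] = weighted / max(wsum, 1.0)
    return pd.DataFrame(rows)


def balance_report(smd_table: pd.DataFrame, path) -> None:
    """Plain-text balance report of pre/post-stratification SMDs."""
    lines = ["Standardized mean differences (cases vs controls)", "-" * 50]
    for _, r in smd_table.iterrows():
        line = f"{r['covariate']:<28s} crude {r['smd_crude']:+8.4f}"
        if "smd_stratified" in smd_table.columns:
            line += f"   stratified {r['smd_stratified']:+8.4f}"
        lines.append(line)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
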