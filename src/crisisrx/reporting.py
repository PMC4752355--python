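"""Descriptive tables and monthly consumption series.

Reproduces the shape of the study's descriptive outputs on any cohort in
the pipeline's format: cohort characteristics by period, mean (sd)
consumption per stratifier and period with between-period tests (Welch t
for means, chi-square for categoricals), and per-month series of both
outcomes, optionally split by drug class and consumer group.

All means are over consuming person-months: the panel only has rows for
months with at least one dispensing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CRISIS_MONTH

__all__ = [
    "PERIODS",
    "cohort_characteristics",
    "consumption_summary",
    "monthly_series",
    "plot_monthly_series",
]

PERIODS = ("2005-2012", "2005-2008", "2009-2012")


def _period_mask(months: pd.Series, period: str, crisis_month: int):
    if period == "2005-2012":
        return pd.Series(True, index=months.index)
    if period == "2005-2008":
        return months < crisis_month
    if period == "2009-2012":
        return months >= crisis_month
    raise ValueError(f"unknown period {period!r}")


def _welch(x0, x1) -> float:
    x0, x1 = np.asarray(x0, float), np.asarray(x1, float)
    if len(x0) < 2 or len(x1) < 2:
        return np.nan
    if np.ptp(x0) == 0 and np.ptp(x1) == 0 and x0[0] == x1[0]:
        return 1.0
    return float(stats.ttest_ind(x0, x1, equal_var=False).pvalue)


def _chi2(labels0, labels1) -> float:
    tab = pd.crosstab(
        np.concatenate([np.zeros(len(labels0)), np.ones(len(labels1))]),
        np.concatenate([np.asarray(labels0, dtype=object), np.asarray(labels1, dtype=object)]),
    )
    if tab.shape[1] < 2:
        return 1.0
    return float(stats.chi2_contingency(tab).pvalue)


def cohort_characteristics(
    individuals: pd.DataFrame, panel: pd.DataFrame, crisis_month: int = CRISIS_MONTH
) -> pd.DataFrame:
    """Cohort composition per period with between-period comparisons.

    Rows: number of individuals, mean (sd) age, % women, % metabolic
    syndrome, % family in cohort, country distribution, unemployment-quintile
    occupancies.  The p-value column compares 2005-2008 with 2009-2012.
    """
    if panel.empty:
        raise ValueError("empty panel")
    rows = []
    per_frames = {
        p: panel[_period_mask(panel["month"], p, crisis_month)] for p in PERIODS
    }
    for p, f in per_frames.items():
        if f.empty:
            raise ValueError(f"no observations in period {p}")

    def per_individual(frame, col, how="first"):
        return frame.groupby("individual_id")[col].agg(how)

    ns = {p: f["individual_id"].nunique() for p, f in per_frames.items()}
    rows.append({"characteristic": "n_individuals", "level": "",
                 **{p: float(ns[p]) for p in PERIODS}, "p_value": np.nan})

    if "age" in panel.columns:
        ages = {p: per_individual(f, "age", "mean") for p, f in per_frames.items()}
        rows.append({"characteristic": "age_mean", "level": "",
                     **{p: float(a.mean()) for p, a in ages.items()},
                     "p_value": _welch(ages["2005-2008"], ages["2009-2012"])})
        rows.append({"characteristic": "age_sd", "level": "",
                     **{p: float(a.std(ddof=1)) for p, a in ages.items()}, "p_value": np.nan})

    def prop_row(name, col, value):
        per = {p: per_individual(f, col, "first") for p, f in per_frames.items()}
        vals = {p: float((v == value).mean()) for p, v in per.items()}
        pv = _chi2(
            (per["2005-2008"] == value).astype(int), (per["2009-2012"] == value).astype(int)
        )
        rows.append({"characteristic": name, "level": str(value), **vals, "p_value": pv})

    if "sex" in panel.columns:
        prop_row("pct_women", "sex", "female")
    if "ms" in panel.columns:
        per = {p: per_individual(f, "ms", "max") for p, f in per_frames.items()}
        rows.append({"characteristic": "pct_metabolic_syndrome", "level": "",
                     **{p: float(v.mean()) for p, v in per.items()},
                     "p_value": _chi2(per["2005-2008"].astype(int), per["2009-2012"].astype(int))})
    if "family_in_cohort" in panel.columns:
        prop_row("pct_family_in_cohort", "family_in_cohort", True)
    if "country" in panel.columns:
        per = {p: per_individual(f, "country", "first") for p, f in per_frames.items()}
        pv = _chi2(per["2005-2008"], per["2009-2012"])
        for lev in sorted(panel["country"].unique()):
            rows.append({"characteristic": "country", "level": lev,
                         **{p: float((v == lev).mean()) for p, v in per.items()}, "p_value": pv})
    for qcol, name in (("unempl_quintile", "unempl_quintile"),
                       ("unempl_lt_quintile", "unempl_lt_quintile")):
        if qcol in panel.columns:
            per = {p: per_individual(f, qcol, "last") for p, f in per_frames.items()}
            pv = _chi2(per["2005-2008"], per["2009-2012"])
            for q in (1, 2, 3, 4, 5):
                rows.append({"characteristic": name, "level": str(q),
                             **{p: float((v == q).mean()) for p, v in per.items()},
                             "p_value": pv})
    return pd.DataFrame(rows)


_STRATIFIERS = {
    "all": None,
    "consumer_group": "consumer_group",
    "sex": "sex",
    "age_group": "age_group",
    "unempl_quintile": "unempl_quintile",
    "unempl_lt_quintile": "unempl_lt_quintile",
}


def consumption_summary(
    panel: pd.DataFrame,
    stratifiers=("all", "sex", "age_group", "unempl_quintile", "unempl_lt_quintile"),
    outcomes=("n_drugs", "ddd"),
    crisis_month: int = CRISIS_MONTH,
) -> pd.DataFrame:
    """Mean (sd) consumption per stratum and period with Welch p-values.

    The ``consumer_group`` stratifier splits "not consumers before 2009"
    from "always consumers" when the panel has a ``consumer_group`` column.
    """
    work = panel
    rows = []
    for strat in stratifiers:
        if strat not in _STRATIFIERS:
            raise ValueError(f"unknown stratifier {strat!r}")
        col = _STRATIFIERS[strat]
        if col is None:
            groups = [("all", pd.Series(True, index=work.index))]
        else:
            if col not in work.columns:
                raise ValueError(f"panel lacks stratifier column {col!r}")
            groups = [(str(lev), work[col] == lev) for lev in sorted(work[col].unique(), key=str)]
        for lev, mask in groups:
            sub = work[mask]
            for outcome in outcomes:
                vals = {}
                for p in PERIODS:
                    v = sub.loc[_period_mask(sub["month"], p, crisis_month), outcome]
                    vals[p] = v
                if len(vals["2005-2012"]) == 0:
                    continue
                rows.append(
                    {
                        "stratifier": strat,
                        "level": lev,
                        "outcome": outcome,
                        **{
                            f"mean_{p}": float(v.mean()) if len(v) else np.nan
                            for p, v in vals.items()
                        },
                        **{
                            f"sd_{p}": float(v.std(ddof=1)) if len(v) > 1 else np.nan
                            for p, v in vals.items()
                        },
                        "n": int(len(vals["2005-2012"])),
                        "p_value": _welch(vals["2005-2008"], vals["2009-2012"]),
                    }
                )
    return pd.DataFrame(rows)


def monthly_series(panel: pd.DataFrame, groupers: list[str] | None = None) -> pd.DataFrame:
    """Per-month means of both outcomes, optionally within groups."""
    keys = ["month"] + list(groupers or [])
    value_cols = [c for c in ("n_drugs", "ddd", "ddd_anxiolytic", "ddd_antidepressant",
                              "n_drugs_anxiolytic", "n_drugs_antidepressant")
                  if c in panel.columns]
    out = panel.groupby(keys)[value_cols].mean().reset_index()
    return out.sort_values(keys).reset_index(drop=True)


def plot_monthly_series(series: pd.DataFrame, outcome: str, path, group: str | None = None):
    """Line plot of a monthly mean series; writes a PNG artifact."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    if group and group in series.columns:
        for lev, sub in series.groupby(group):
            ax.plot(sub["month"], sub[outcome], label=str(lev))
        ax.legend()
    else:
        ax.plot(series["month"], series[outcome])
    ax.axvline(CRISIS_MONTH - 0.5, color="gray", ls="--", lw=1)
    ax.set_xlabel("study month (1 = Jan 2005)")
    ax.set_ylabel(outcome)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
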