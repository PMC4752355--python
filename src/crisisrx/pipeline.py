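"""Single-command pipeline orchestration.

Runs synthetic -> ddd -> covariates -> propensity -> panel_model ->
rr_analysis -> reporting on either a synthetic cohort block or real-format
CSV inputs, writing all artifacts plus a manifest (config hash, seed, stage
list) into the output directory.  Identical config + seed reproduces the
manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import ddd as ddd_mod
from . import propensity as prop
from . import reporting
from .io import CRISIS_MONTH, write_table
from .model import ModelSpec, PanelGLMM
from .rr import relative_risk
from .synthetic import CohortConfig, ParameterSet, generate_individuals, simulate_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("synthetic", "ddd", "covariates", "propensity", "model", "rr", "report")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config`` for YAML)."""

    outdir: str = "artifacts"
    seed: int = 0
    synthetic: dict | None = None      # CohortConfig overrides
    inputs: dict | None = None         # paths: prescriptions/individuals/clinical/registry
    model: dict = field(default_factory=dict)       # ModelSpec overrides
    sampler: dict = field(default_factory=lambda: {"draws": 500, "warmup": 500})
    propensity: dict = field(default_factory=lambda: {"n_strata": 5})
    stages: tuple = ALL_STAGES
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' and 'inputs' must be given")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    d = asdict(config)
    d.pop("outdir", None)  # where artifacts land does not change what they are
    d.pop("log_level", None)
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _cohort_config(config: PipelineConfig) -> CohortConfig:
    over = dict(config.synthetic or {})
    for key in ("params_count", "params_ddd"):
        if key in over and isinstance(over[key], dict):
            over[key] = ParameterSet(**over[key])
    over.setdefault("seed", config.seed)
    over.setdefault("n_individuals", 500)
    return CohortConfig(**over)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns {artifact name -> path}."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    artifacts: dict[str, str] = {}
    stages = [s for s in ALL_STAGES if s in config.stages]

    # ---- inputs ----------------------------------------------------------
    if config.synthetic is not None:
        cc = _cohort_config(config)
        individuals = generate_individuals(cc)
        sim = simulate_panel(individuals, cc)
        panel, prescriptions, clinical = sim.panel, sim.prescriptions, sim.clinical
        crisis = cc.crisis_month
        if "synthetic" in stages:
            for name, df in (("individuals", individuals.drop(columns=["unempl_frailty"])),
                             ("panel", panel), ("prescriptions", prescriptions),
                             ("clinical", clinical)):
                p = outdir / f"{name}.csv"
                write_table(df, p)
                artifacts[name] = str(p)
    else:
        from .io import read_table

        paths = config.inputs
        prescriptions = read_table(paths["prescriptions"], "prescriptions")
        individuals = read_table(paths["individuals"], "individuals")
        clinical = read_table(paths["clinical"], "clinical") if "clinical" in paths else None
        panel = None
        crisis = CRISIS_MONTH

    registry = (
        ddd_mod.DDDRegistry.from_csv(config.inputs["registry"])
        if config.inputs and "registry" in config.inputs
        else ddd_mod.load_default_registry()
    )

    # ---- ddd aggregation -------------------------------------------------
    if "ddd" in stages:
        agg = ddd_mod.aggregate_monthly(prescriptions, registry, by_class=True)
        p = outdir / "consumption.csv"
        write_table(agg, p)
        artifacts["consumption"] = str(p)
        if panel is None:
            panel = agg
        else:
            class_cols = [c for c in agg.columns if c.endswith(("anxiolytic", "antidepressant"))]
            panel = panel.merge(
                agg[["individual_id", "month"] + class_cols],
                on=["individual_id", "month"], how="left",
            )
            panel[class_cols] = panel[class_cols].fillna(0)

    # ---- covariates ------------------------------------------------------
    if "covariates" in stages and clinical is not None and "unemployed" in clinical.columns:
        base = individuals.set_index("individual_id")
        feat = clinical[["individual_id", "month"]].copy()
        feat["post"] = (feat["month"] >= crisis).astype(float)
        feat["female"] = (feat["individual_id"].map(base["sex"]) == "female").astype(float)
        feat["foreign"] = (feat["individual_id"].map(base["country"]) != "spain").astype(float)
        age0 = (pd.Timestamp("2005-01-01") - pd.to_datetime(base["birth_date"])).dt.days / 365.25
        feat["age"] = feat["individual_id"].map(age0) + (feat["month"] - 1) / 12.0
        cols = ["post", "female", "foreign", "age"]
        scored = cov.estimate_unemployment_probability(feat, clinical["unemployed"], cols)
        unem = feat.assign(p_unemployed=scored)
        unem["quintile_refit"] = cov.assign_quintiles(unem["p_unemployed"])
        p = outdir / "unemployment.csv"
        write_table(unem, p)
        artifacts["unemployment"] = str(p)

    # ---- propensity ------------------------------------------------------
    strata_by_id = None
    if "propensity" in stages:
        case = prop.label_case_control(panel, crisis, individuals=individuals)
        base = individuals.set_index("individual_id")
        X = pd.DataFrame(
            {
                "female": (base["sex"] == "female").astype(float),
                "family_in_cohort": base["family_in_cohort"].astype(float),
                "foreign": (base["country"] != "spain").astype(float),
            },
            index=base.index,
        )
        ps = prop.estimate_propensity(X, case.reindex(X.index), list(X.columns))
        strata = prop.stratify(ps, n_strata=int(config.propensity.get("n_strata", 5)),
                               case_flag=case.reindex(X.index))
        res = pd.DataFrame(
            {"individual_id": X.index, "case": case.reindex(X.index).to_numpy(),
             "propensity": ps.to_numpy(), "stratum": strata.to_numpy()}
        )
        p = outdir / "propensity.csv"
        write_table(res, p)
        artifacts["propensity"] = str(p)
        smd = prop.standardized_mean_differences(X, case.reindex(X.index), list(X.columns),
                                                 strata=strata)
        prop.balance_report(smd, outdir / "balance_report.txt")
        artifacts["balance_report"] = str(outdir / "balance_report.txt")
        strata_by_id = res.set_index("individual_id")["stratum"]
        panel = panel.merge(res[["individual_id", "stratum"]], on="individual_id", how="left")
        grp = np.where(
            panel["individual_id"].map(dict(zip(res["individual_id"], res["case"]))),
            "always_consumers", "not_consumers_before_2009",
        )
        panel["consumer_group"] = grp

    # ---- panel model + rr ------------------------------------------------
    results = {}
    if "model" in stages:
        spec_over = dict(config.model)
        terms = spec_over.pop("fixed_terms", ["sex", "post2009"])
        if strata_by_id is not None and "stratum" in panel.columns and panel["stratum"].nunique() > 1:
            if "stratum" not in terms:
                terms = terms + ["stratum"]
        for family, outcome in (("poisson_count", "n_drugs"), ("gaussian_ddd", "ddd")):
            spec = ModelSpec(family=family, fixed_terms=list(terms),
                             crisis_month=crisis, **spec_over)
            model = PanelGLMM(panel, spec, outcome=outcome)
            res = model.fit(seed=config.seed, **config.sampler)
            results[family] = res
            res.summary().to_csv(outdir / f"posterior_{outcome}.csv", index=False)
            artifacts[f"posterior_{outcome}"] = str(outdir / f"posterior_{outcome}.csv")

    if "rr" in stages and results:
        rows = []
        for family, res in results.items():
            est = relative_risk(res, force=config.force)
            rows.append({"outcome": est.outcome, "family": family, "rr": est.rr,
                         "ci_low": est.ci_low, "ci_high": est.ci_high,
                         "significant": est.significant})
            path_df = res.monthly_rr_path(force=config.force)
            path_df.to_csv(outdir / f"rr_path_{family}.csv", index=False)
            artifacts[f"rr_path_{family}"] = str(outdir / f"rr_path_{family}.csv")
        pd.DataFrame(rows).to_csv(outdir / "rr_table.csv", index=False)
        artifacts["rr_table"] = str(outdir / "rr_table.csv")

    # ---- reporting -------------------------------------------------------
    if "report" in stages and panel is not None:
        strat = ["all"] + [s for s in ("consumer_group", "sex", "age_group",
                                       "unempl_quintile", "unempl_lt_quintile")
                           if s in panel.columns]
        summ = reporting.consumption_summary(panel, stratifiers=strat, crisis_month=crisis)
        summ.to_csv(outdir / "consumption_summary.csv", index=False)
        artifacts["consumption_summary"] = str(outdir / "consumption_summary.csv")
        if {"sex", "age"} & set(panel.columns):
            chars = reporting.cohort_characteristics(individuals, panel, crisis_month=crisis)
            chars.to_csv(outdir / "cohort_characteristics.csv", index=False)
            artifacts["cohort_characteristics"] = str(outdir / "cohort_characteristics.csv")
        series = reporting.monthly_series(panel)
        series.to_csv(outdir / "monthly_series.csv", index=False)
        artifacts["monthly_series"] = str(outdir / "monthly_series.csv")
        figdir = outdir / "figs"
        figdir.mkdir(exist_ok=True)
        for outc in ("n_drugs", "ddd"):
            if outc in series.columns:
                reporting.plot_monthly_series(series, outc, figdir / f"{outc}.png")
                artifacts[f"fig_{outc}"] = str(figdir / f"{outc}.png")

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": stages,
        "artifacts": sorted(artifacts),
        "version": "0.1.0",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
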