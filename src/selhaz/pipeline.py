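"""End-to-end orchestration of the seven analysis stages.

simulate -> density surfaces -> latent health -> risk aversion -> adverse
selection -> moral hazard -> PSM-DID, with every stage writing a plain-text
artifact (CSV/YAML/JSON; density surfaces as an npz archive) under the run
directory and a single JSON report collecting the summary blocks.  Stages can
be toggled off, in which case downstream stages read the cached artifacts.
All randomness derives from the single seed recorded in the report.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import density as density_mod
from . import did as did_mod
from . import hazard as hazard_mod
from . import riskaversion as ra
from . import selection as selection_mod
from . import structural
from .exceptions import SelhazError
from .synthetic import SyntheticConfig, generate_population, records_to_csv

REPORT_SCHEMA_VERSION = 1

#: individual + province covariates entering the propensity model and the
#: DID control set
PSM_COVARIATES = [
    "age", "gender_num", "income", "education_num", "married_num",
    "children_num", "theta", "smoke_num", "drink_num", "exercise_num",
    "nap_num", "late_sleep_num", "log_gdp_pc", "med_personnel", "gp_per_10k",
    "beds_per_1k", "uebmi_ratio", "urrbmi_ratio",
]


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    n_per_wave: int = 2000
    a_jitter_sd: float = 0.05
    bandwidth_method: str = "silverman"
    atom: str = "mixture"
    theta_route: str = "auto"
    grid_sizes: tuple = (20, 40, 50)
    bootstrap_B: int = 0
    ks_method: str = "asymptotic"
    match_with_replacement: bool = True
    caliper: float | None = None
    stages: dict = field(
        default_factory=lambda: {
            s: True
            for s in (
                "simulate", "density", "theta", "gamma",
                "adverse_selection", "moral_hazard", "did",
            )
        }
    )
    synthetic_overrides: dict = field(default_factory=dict)

    def synthetic_config(self) -> SyntheticConfig:
        cfg = SyntheticConfig(
            n_per_wave=self.n_per_wave, seed=self.seed, a_jitter_sd=self.a_jitter_sd,
        )
        for k, v in self.synthetic_overrides.items():
            setattr(cfg, k, v)
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return None  # frames are exported to CSV artifacts, not the report
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def _prepare_did_frame(records: pd.DataFrame, theta: pd.Series,
                       mh: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df["theta"] = theta.to_numpy()
    for col in ("married", "children", "smoke", "drink", "exercise", "nap",
                "late_sleep"):
        df[f"{col}_num"] = df[col].astype(float)
    df["gender_num"] = (df["gender"] == "male").astype(float)
    df["education_num"] = (df["education_level"] == "high").astype(float)
    df = df[df["insured"]].merge(
        mh[["id", "year", "over_consumption", "share"]], on=["id", "year"], how="left"
    )
    df["over_consumption"] = df["over_consumption"].fillna(0.0)
    df["share"] = df["share"].fillna(0.0)
    df["log1p_over"] = np.log1p(df["over_consumption"])
    out_m = np.where(df["service_type"] == "general_outpatient", df["expenditure"], 0.0)
    in_m = np.where(df["service_type"] == "inpatient", df["expenditure"], 0.0)
    df["log1p_outpatient"] = np.log1p(out_m)
    df["log1p_inpatient"] = np.log1p(in_m)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    os.makedirs(config.outdir, exist_ok=True)
    art = lambda name: os.path.join(config.outdir, name)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
        "timing": {},
    }
    scfg = config.synthetic_config()

    def timed(stage, fn):
        t0 = time.perf_counter()
        out = fn()
        report["timing"][stage] = round(time.perf_counter() - t0, 3)
        return out

    # 1. simulate ----------------------------------------------------------
    def _simulate():
        if config.stages.get("simulate", True):
            df = generate_population(scfg)
            records_to_csv(df, art("records.csv"))
            with open(art("config.yaml"), "w") as fh:
                fh.write(scfg.to_yaml())
        else:
            df = pd.read_csv(art("records.csv"), float_precision="round_trip")
        return df

    try:
        records = timed("simulate", _simulate)
    except SelhazError as err:
        raise SelhazError(f"stage simulate: {err}") from err
    report["stages"]["simulate"] = {
        "n_records": int(len(records)),
        "share_insured": float(records["insured"].mean()),
        "share_zero_expenditure": float((records["expenditure"] == 0).mean()),
    }

    # 2. density surfaces --------------------------------------------------
    def _density():
        if config.stages.get("density", True):
            surfaces, skipped = density_mod.fit_all_strata(
                records, bandwidth_method=config.bandwidth_method, atom=config.atom
            )
            density_mod.save_surfaces(surfaces, art("surfaces.npz"))
            return surfaces, skipped
        return density_mod.load_surfaces(art("surfaces.npz")), []

    try:
        surfaces, skipped = timed("density", _density)
    except SelhazError as err:
        raise SelhazError(f"stage density: {err}") from err
    report["stages"]["density"] = {
        "strata": {
            "|".join(map(str, k)): {
                "h_m": s.h_m, "h_a": s.h_a, "n": s.n_obs,
                "bandwidth_method": s.bandwidth_method,
            }
            for k, s in surfaces.items()
        },
        "skipped": ["|".join(map(str, k)) for k in skipped],
    }

    # 3+4. latent health & risk aversion (jointly seeded by the gamma search)
    def _gamma():
        if not config.stages.get("gamma", True):
            with open(art("gammas.yaml")) as fh:
                return yaml.safe_load(fh)
        sub = records.apply(
            lambda r: ra.subgroup_assign(r["gender"], r["education_level"]), axis=1
        )
        out = {}
        for label in sorted(sub.unique()):
            grp = records[sub == label]
            res = ra.run_grid_sizes(
                grp, surfaces=surfaces, schedule=scfg.schedule,
                sizes=config.grid_sizes, route=config.theta_route,
                subgroup=label, bootstrap_B=config.bootstrap_B, seed=config.seed,
            )
            out[label] = {
                "average": list(res["average"]),
                "per_grid": {
                    int(size): {
                        "gamma1": est.gamma1, "gamma2": est.gamma2,
                        "objective": est.objective,
                        "se_gamma1": est.se_gamma1, "se_gamma2": est.se_gamma2,
                        "n_wave1": est.n_wave1, "n_wave2": est.n_wave2,
                    }
                    for size, est in res["per_grid"].items()
                },
            }
        with open(art("gammas.yaml"), "w") as fh:
            yaml.safe_dump(_jsonable(out), fh, sort_keys=True)
        return out

    try:
        gamma_report = timed("gamma", _gamma)
    except SelhazError as err:
        raise SelhazError(f"stage gamma: {err}") from err
    report["stages"]["gamma"] = gamma_report
    gammas_hat = {
        label: tuple(block["average"]) for label, block in gamma_report.items()
    }

    def _theta():
        if not config.stages.get("theta", True):
            return pd.read_csv(art("theta.csv"), float_precision="round_trip")
        tbl = structural.estimate_theta_table(
            records, surfaces, gammas_hat, schedule=scfg.schedule,
            route=config.theta_route,
        )
        tbl.to_csv(art("theta.csv"), index=False, float_format="%.17g")
        return tbl

    try:
        theta_tbl = timed("theta", _theta)
    except SelhazError as err:
        raise SelhazError(f"stage theta: {err}") from err
    report["stages"]["theta"] = {
        "n": int(len(theta_tbl)),
        "n_infeasible": int(theta_tbl["infeasible"].sum()),
        "clip_rate": float(theta_tbl["clipped"].mean()),
        "mean_theta": float(theta_tbl["theta"].dropna().mean()),
    }

    # 5. adverse selection -------------------------------------------------
    def _adverse():
        if not config.stages.get("adverse_selection", True):
            with open(art("as_report.json")) as fh:
                return json.load(fh)
        out = {}
        ok = ~theta_tbl["infeasible"]
        for year in sorted(records["year"].unique()):
            sel = ok & (theta_tbl["year"] == year)
            th = theta_tbl.loc[sel, "theta"].to_numpy()
            ins = theta_tbl.loc[sel, "insured"].to_numpy(dtype=bool)
            summ = selection_mod.summarize_theta(th, ins)
            for label, block in summ.items():
                if block:
                    block["ecdf"].to_csv(
                        art(f"theta_ecdf_{year}_{label}.csv"), index=False
                    )
                    block["histogram"].to_csv(
                        art(f"theta_hist_{year}_{label}.csv"), index=False
                    )
            ks = selection_mod.ks_one_sided(
                th[ins], th[~ins], method=config.ks_method, seed=config.seed
            )
            out[int(year)] = {
                "summary": {
                    k: (None if v is None else {
                        kk: vv for kk, vv in v.items()
                        if kk not in ("ecdf", "histogram")
                    })
                    for k, v in summ.items()
                },
                "ks": _jsonable(ks),
            }
        with open(art("as_report.json"), "w") as fh:
            json.dump(_jsonable(out), fh, indent=1)
        return out

    try:
        as_report = timed("adverse_selection", _adverse)
    except SelhazError as err:
        raise SelhazError(f"stage adverse_selection: {err}") from err
    report["stages"]["adverse_selection"] = as_report

    # 6. moral hazard ------------------------------------------------------
    def _hazard():
        if not config.stages.get("moral_hazard", True):
            with open(art("mh_report.json")) as fh:
                return json.load(fh), pd.read_csv(art("slutsky.csv"), float_precision="round_trip")
        ins = records[records["insured"]].copy()
        # theta entering the counterfactual: realized-rate closed form, which
        # rationalizes the observed bundle at price 1 - a1 (see methods note)
        tbl = structural.estimate_theta_table(
            ins, None, gammas_hat, schedule=scfg.schedule, route="realized"
        )
        feasible = ~tbl["infeasible"].to_numpy()
        ins_f = ins[feasible]
        sub = ins_f.apply(
            lambda r: ra.subgroup_assign(r["gender"], r["education_level"]), axis=1
        )
        g1 = np.array([gammas_hat[s][0] for s in sub])
        g2 = np.array([gammas_hat[s][1] for s in sub])
        slut = hazard_mod.slutsky_decompose(
            ins_f, tbl.loc[feasible, "theta"].to_numpy(), g1, g2
        )
        slut.to_csv(art("slutsky.csv"), index=False, float_format="%.17g")
        summary = hazard_mod.incidence_and_totals(slut)
        joined = slut.join(
            ins_f[["age", "income", "education_level", "exercise", "smoke",
                   "gender", "married"]]
        )
        het = {}
        for var in ("age65", "income", "education", "health", "exercise",
                    "smoking", "gender", "marital"):
            block = hazard_mod.heterogeneity_ecdf(joined, var)
            for label in ("yes", "no"):
                g = block["groups"][label]
                pd.DataFrame(
                    {"share": g["share_sorted"], "ecdf": g["ecdf"]}
                ).to_csv(art(f"mh_ecdf_{var}_{label}.csv"), index=False)
            het[var] = {
                "max_gap": block["max_gap"],
                "n_yes": block["groups"]["yes"]["n"],
                "n_no": block["groups"]["no"]["n"],
            }
        out = {"summary": summary, "heterogeneity": het,
               "n_infeasible": int((~feasible).sum())}
        with open(art("mh_report.json"), "w") as fh:
            json.dump(_jsonable(out), fh, indent=1)
        return out, slut

    try:
        mh_report, slut = timed("moral_hazard", _hazard)
    except SelhazError as err:
        raise SelhazError(f"stage moral_hazard: {err}") from err
    report["stages"]["moral_hazard"] = mh_report

    # 7. PSM-DID -----------------------------------------------------------
    def _did():
        if not config.stages.get("did", True):
            with open(art("did_report.json")) as fh:
                return json.load(fh)
        df = _prepare_did_frame(records, theta_tbl["theta"].fillna(0.0), slut)
        out = {}
        for outcome, is_log in [
            ("log1p_over", True), ("share", False),
            ("log1p_outpatient", True), ("log1p_inpatient", True),
        ]:
            res, diags = did_mod.psm_did(
                df, outcome, PSM_COVARIATES, controls=PSM_COVARIATES,
                with_replacement=config.match_with_replacement,
                caliper=config.caliper, log_outcome=is_log,
            )
            out[outcome] = {
                "coefficient": res.coefficient, "se": res.se, "n": res.n,
                "log_outcome": res.log_outcome,
                "dropped_columns": res.dropped_columns,
                "match": {
                    str(yr): {
                        "max_abs_smd_before": float(d.smd_before.abs().max()),
                        "max_abs_smd_after": float(d.smd_after.abs().max()),
                        "n_matched": d.n_treated_matched,
                        "n_dropped_support": d.n_dropped_support,
                    }
                    for yr, d in diags.items()
                },
            }
        with open(art("did_report.json"), "w") as fh:
            json.dump(_jsonable(out), fh, indent=1)
        return out

    try:
        report["stages"]["did"] = timed("did", _did)
    except SelhazError as err:
        raise SelhazError(f"stage did: {err}") from err

    with open(art("report.json"), "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    return report
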