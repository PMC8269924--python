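"""End-to-end pipeline: simulate -> build -> fit -> sensitivity -> disclose.

Each stage writes its outputs to disk and the next stage consumes only those
serialised outputs, so any stage can be re-run in isolation.  A run manifest
records configuration, package version and a content hash for every output
file; reruns with the same configuration and seed produce identical
manifests.
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

from . import __version__
from .cohort import CohortSpec, build_person_period, risk_table, select_entry_cohort
from .disclosure import disclose_percentage, disclose_table, round_count
from .model import (
    baseline_hazards,
    effect_estimates,
    fit,
    pattern_curve,
    pseudo_r2,
)
from .records import read_records, write_records
from .sensitivity import compare_estimators, km_estimate, life_table
from .synthetic import CohortConfig, CovariateSpec, generate_cohort, published_cohort_scenario

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("trainsurv")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``records_path`` (pre-existing observation records CSV) or
    ``simulate`` (a CohortConfig, or None for the bundled scenario preset)
    feeds the cohort builder.  ``patterns`` lists covariate patterns whose
    survival curves are tabulated alongside the baseline.
    """

    out_dir: str | Path = "trainsurv_out"
    seed: int = 0
    records_path: str | Path | None = None
    simulate: CohortConfig | None = None
    entry_window: tuple[int, int] = (2012, 2017)
    horizon_year: int = 2018
    restrict_pmq: str | None = None
    covariates: tuple[str, ...] = ("gender", "pmq_region")
    interactions: tuple[tuple[str, str], ...] = ()
    patterns: tuple[dict, ...] = ()
    disclosure: bool = True
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "simulate"})
    if sim is not None:
        specs = tuple(
            CovariateSpec(s["name"], s["prevalence"], s["effect"])
            for s in sim.pop("covariate_specs", [])
        )
        sim["entry_year_weights"] = {
            int(k): float(v) for k, v in sim["entry_year_weights"].items()
        }
        sim["baseline_hazards"] = tuple(sim["baseline_hazards"])
        cfg.simulate = CohortConfig(covariate_specs=specs, **sim)
    if isinstance(cfg.entry_window, list):
        cfg.entry_window = tuple(cfg.entry_window)
    cfg.covariates = tuple(cfg.covariates)
    cfg.interactions = tuple(tuple(p) for p in cfg.interactions)
    cfg.patterns = tuple(cfg.patterns)
    return cfg


def _fit_summary(fit_result, curves: dict) -> dict:
    cs, nk = pseudo_r2(fit_result)
    se = fit_result.se()
    effects = [asdict(e) for e in effect_estimates(fit_result)]
    return {
        "coefficients": {
            name: float(v)
            for name, v in fit_result.coef().items()
        },
        "standard_errors": {name: float(v) for name, v in se.items()},
        "effects": effects,
        "minus2LL": fit_result.minus2LL,
        "null_minus2LL": fit_result.null_minus2LL,
        "pseudo_r2_cox_snell": cs,
        "pseudo_r2_nagelkerke": nk,
        "n_rows": fit_result.n_rows,
        "n_persons": fit_result.n_persons,
        "n_dropped_rows": fit_result.n_dropped_rows,
        "n_dropped_persons": fit_result.n_dropped_persons,
        "converged": fit_result.converged,
        "curves": curves,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "setup"
    try:
        # ---- simulate / load -------------------------------------------------
        stage = "simulate"
        if config.records_path is not None:
            records = read_records(config.records_path)
            log.info("loaded %d records from %s", len(records), config.records_path)
        else:
            sim = config.simulate or published_cohort_scenario(seed=config.seed)
            if config.simulate is not None and config.seed != sim.seed:
                sim = sim.replace(seed=config.seed)
            records = generate_cohort(sim)
            log.info("simulated %d records for %d trainees", len(records), sim.n_trainees)
        records_csv = out / "records.csv"
        write_records(records, records_csv)
        outputs.append(records_csv)

        # ---- build -----------------------------------------------------------
        stage = "build"
        records = read_records(records_csv)
        spec = CohortSpec(
            entry_window=config.entry_window,
            horizon_year=config.horizon_year,
            restrict_pmq=config.restrict_pmq,
        )
        cohort = select_entry_cohort(records, spec)
        pp = build_person_period(records, cohort, spec)
        risk = risk_table(pp)
        cohort_csv, pp_csv, risk_csv = (
            out / "cohort.csv",
            out / "person_periods.csv",
            out / "risk_table.csv",
        )
        cohort.to_csv(cohort_csv, index=False)
        pp.to_csv(pp_csv, index=False)
        risk.to_csv(risk_csv, index=False)
        outputs += [cohort_csv, pp_csv, risk_csv]
        log.info("cohort of %d persons, %d person-period rows", len(cohort), len(pp))

        # ---- fit -------------------------------------------------------------
        stage = "fit"
        pp = pd.read_csv(pp_csv, dtype={"person_id": object})
        base_fit = fit(pp)  # intercepts-only
        base_curve = baseline_hazards(base_fit)
        cov_fit = fit(pp, covariates=config.covariates, interactions=config.interactions)

        curve_rows = [
            {
                "pattern": "baseline (intercepts only)",
                "time": int(t),
                "hazard": float(h),
                "survival": float(s),
            }
            for t, h, s in zip(
                range(1, base_fit.max_time + 1), base_curve.hazards, base_curve.survival
            )
        ]
        curves_json = {}
        for pattern in config.patterns:
            c = pattern_curve(cov_fit, pattern)
            label = ", ".join(f"{k}={v}" for k, v in pattern.items())
            curves_json[label] = {
                "hazards": c.hazards.tolist(),
                "survival": c.survival.tolist(),
            }
            curve_rows += [
                {"pattern": label, "time": int(t), "hazard": float(h), "survival": float(s)}
                for t, h, s in zip(range(1, cov_fit.max_time + 1), c.hazards, c.survival)
            ]
        curves_csv = out / "survival_curves.csv"
        pd.DataFrame(curve_rows).to_csv(curves_csv, index=False)
        fit_json = out / "fit.json"
        fit_json.write_text(json.dumps(_fit_summary(cov_fit, curves_json), indent=2))
        outputs += [curves_csv, fit_json]

        # ---- sensitivity -----------------------------------------------------
        stage = "sensitivity"
        risk = pd.read_csv(risk_csv)
        pp = pd.read_csv(pp_csv, dtype={"person_id": object})
        lt = life_table(risk)
        km = km_estimate(pp, max_time=base_fit.max_time)
        agreement = compare_estimators(base_curve, km, lt)
        lt_csv, km_csv, agree_json = (
            out / "life_table.csv",
            out / "km_curve.csv",
            out / "agreement.json",
        )
        lt.to_csv(lt_csv, index=False)
        pd.DataFrame(
            {
                "time": km.times,
                "survival": km.survival,
                "at_risk": km.at_risk,
                "events": km.events,
            }
        ).to_csv(km_csv, index=False)
        agree_json.write_text(json.dumps(agreement, indent=2))
        outputs += [lt_csv, km_csv, agree_json]

        # ---- disclose --------------------------------------------------------
        stage = "disclose"
        if config.disclosure:
            risk = pd.read_csv(risk_csv)
            disclosed = disclose_table(risk, ["n_at_risk", "events", "censored"])
            summary_rows = [
                {
                    "quantity": "cohort size",
                    "value": round_count(len(cohort)),
                }
            ]
            covs = pp.sort_values(["person_id", "time"]).groupby("person_id").first()
            for cov, category in (("gender", "female"), ("pmq_region", "UK")):
                if cov in covs.columns:
                    num = int((covs[cov] == category).sum())
                    denom = int(covs[cov].notna().sum())
                    pct = disclose_percentage(num, denom)
                    summary_rows.append(
                        {"quantity": f"% {category} ({cov})", "value": pct}
                    )
            disclosed_csv = out / "disclosed_risk_table.csv"
            summary_csv = out / "disclosed_summary.csv"
            disclosed.to_csv(disclosed_csv, index=False)
            pd.DataFrame(summary_rows).to_csv(summary_csv, index=False)
            outputs += [disclosed_csv, summary_csv]
    except Exception as exc:
        partial = [str(p) for p in outputs if p.exists()]
        raise RuntimeError(
            f"pipeline stage '{stage}' failed: {exc}; partial outputs: {partial}"
        ) from exc

    # ---- manifest -----------------------------------------------------------
    manifest = {
        "package": "trainsurv",
        "version": __version__,
        "seed": int(config.seed),
        "stages": ["simulate", "build", "fit", "sensitivity", "disclose"],
        "config": {
            "entry_window": list(config.entry_window),
            "horizon_year": config.horizon_year,
            "restrict_pmq": config.restrict_pmq,
            "covariates": list(config.covariates),
            "interactions": [list(p) for p in config.interactions],
            "disclosure": config.disclosure,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
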