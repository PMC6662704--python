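"""End-to-end orchestration: simulate -> rates -> ages -> fits -> budget -> model.

``run_all`` executes every stage on synthetic (or user-supplied) CSV tables
and writes all intermediate products plus a JSON report whose summary table
mirrors the per-reservoir presentation of the study design: transition age,
transition depth and beyond-transition share as mean ± sd across cores.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, agemodel, decayfit, gascalc, globalmodel, lifetime, synthdata


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    replicate_cv: float = 0.086
    ln_residual_sd: float = float(np.sqrt(0.28))


class ExclusionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = Field(default=1, ge=0, le=2)
    rate_threshold: float = 0.5
    surface_top_cm: float = 2.0


class LifetimeSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lifetime_years: float = Field(default=100.0, gt=0)
    deposition_interval_years: float = Field(default=1.0, gt=0)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "sedch4_out"
    slices_csv: str | None = None     # user data; None -> simulate
    vials_csv: str | None = None
    criterion_angle_deg: float = 179.0
    chem_t_total_days: float = 739.0
    noise: NoiseConfig = NoiseConfig()
    exclusion: ExclusionConfig = ExclusionConfig()
    lifetime: LifetimeSection = LifetimeSection()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


REQUIRED_SLICE_COLS = [
    "slice_id", "reservoir", "core_id", "slice_top_cm", "slice_bottom_cm",
    "total_depth_cm", "closure_year", "sampling_date", "water_content_frac",
    "tc_pct_start", "tn_pct_start", "tc_pct_end", "tn_pct_end", "dry_mass_g"]
REQUIRED_VIAL_COLS = [
    "core_id", "slice_id", "replicate", "occasion", "day_start", "day_end",
    "temp_K", "pressure_before_atm", "pressure_after_atm", "headspace_ml",
    "liquid_ml", "ch4_ppm_start", "ch4_ppm_end", "co2_ppm_start",
    "co2_ppm_end"]


def validate_inputs(slices_csv, vials_csv) -> list[str]:
    """Schema/invariant check of input CSVs; returns violation messages."""
    violations: list[str] = []
    try:
        slices = pd.read_csv(slices_csv)
    except OSError as exc:
        raise OSError(f"cannot read slices table: {exc}") from exc
    try:
        vials = pd.read_csv(vials_csv)
    except OSError as exc:
        raise OSError(f"cannot read vials table: {exc}") from exc

    for col in REQUIRED_SLICE_COLS:
        if col not in slices.columns:
            violations.append(f"slices: missing column {col!r}")
    for col in REQUIRED_VIAL_COLS:
        if col not in vials.columns:
            violations.append(f"vials: missing column {col!r}")
    if violations:
        return violations

    if (slices["slice_bottom_cm"] <= slices["slice_top_cm"]).any():
        violations.append("slices: slice_bottom_cm <= slice_top_cm")
    if (slices["slice_bottom_cm"] > slices["total_depth_cm"] + 1e-9).any():
        violations.append("slices: slice extends below total sediment depth")
    for col in ("dry_mass_g", "total_depth_cm"):
        if (slices[col] <= 0).any():
            violations.append(f"slices: non-positive {col}")
    for col in ("tc_pct_start", "tn_pct_start", "tc_pct_end", "tn_pct_end"):
        if (slices[col] < 0).any():
            violations.append(f"slices: negative {col}")
    if slices["slice_id"].duplicated().any():
        violations.append("slices: duplicate slice_id")

    for col in ("headspace_ml", "liquid_ml", "pressure_before_atm",
                "pressure_after_atm", "temp_K"):
        if (vials[col] <= 0).any():
            violations.append(f"vials: non-positive {col}")
    if (vials["pressure_after_atm"] < vials["pressure_before_atm"]).any():
        violations.append("vials: pressure_after_atm < pressure_before_atm")
    if (vials["day_end"] <= vials["day_start"]).any():
        violations.append("vials: day_end <= day_start")
    unknown = set(vials["slice_id"]) - set(slices["slice_id"])
    if unknown:
        violations.append(f"vials: slice ids absent from slices table: "
                          f"{sorted(unknown)[:5]}")
    return violations


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute all pipeline stages; returns the run report (also written).

    Partial outputs are retained if a later stage fails.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "sedch4_version": __version__,
        "stages": {},
        "warnings": [],
    }
    caught: list[str] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self._w = warnings.catch_warnings(record=True)
                self._rec = self._w.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                for w in self._rec:
                    caught.append(f"{name}: {w.message}")
                self._w.__exit__(None, None, None)
                if exc is not None:
                    report["warnings"] = caught
                    _write_report(out, report)
                    raise StageError(name, exc) from exc
                return False
        return _Ctx()

    noise = synthdata.NoiseSpec(replicate_cv=config.noise.replicate_cv,
                                ln_residual_sd=config.noise.ln_residual_sd,
                                seed=config.seed)

    with _stage("simulate"):
        if config.slices_csv and config.vials_csv:
            slices = pd.read_csv(config.slices_csv)
            vials = pd.read_csv(config.vials_csv)
            truth = None
        else:
            slices, truth = synthdata.generate_design(noise=noise)
            vials = synthdata.generate_incubation(slices, truth, noise=noise)
            synthdata.write_outputs(slices, vials, truth, out, config.seed)
        report["stages"]["simulate"] = {"n_slices": len(slices),
                                        "n_vial_rows": len(vials)}

    with _stage("rates"):
        rates = gascalc.compute_rates(vials, slices)
        rates = agemodel.annotate_rates(rates, slices,
                                        t_total_days=config.chem_t_total_days)
        rule = gascalc.ExclusionRule(k=config.exclusion.k,
                                     rate_threshold=config.exclusion.rate_threshold,
                                     surface_top_cm=config.exclusion.surface_top_cm)
        rates = gascalc.apply_exclusions(rates, rule)
        pooled = gascalc.pool_replicates(rates)
        rates.to_csv(out / "rates.csv", index=False)
        pooled.to_csv(out / "rates_pooled.csv", index=False)
        n_excl = int(rates["excluded"].sum())
        report["stages"]["rates"] = {
            "n_rows": len(rates), "n_excluded": n_excl,
            "n_used": len(rates) - n_excl,
            "n_pooled": len(pooled)}
        assert n_excl + (len(rates) - n_excl) == len(rates)

    with _stage("fit_decay"):
        fits = decayfit.fit_all_cores(pooled)
        fits.to_csv(out / "decay_fits.csv", index=False)
        report["stages"]["fit_decay"] = {
            "n_cores": len(fits), "n_converged": int(fits["converged"].sum())}

    with _stage("transition"):
        geo = slices.drop_duplicates("core_id").set_index("core_id")
        trows = []
        for rec in fits.itertuples(index=False):
            if not rec.converged:
                trows.append(dict(reservoir=rec.reservoir, core_id=rec.core_id,
                                  transition_age_y=np.nan,
                                  transition_depth_cm=np.nan))
                continue
            fit = decayfit.DecayFit(rec.core_id, rec.a, rec.b, rec.c, rec.rss,
                                    rec.n_points, rec.converged)
            tr = decayfit.transition_age(fit, config.criterion_angle_deg)
            g = geo.loc[rec.core_id]
            res_age = agemodel.reservoir_age_years(g["closure_year"],
                                                   g["sampling_date"])
            depth = decayfit.transition_depth(tr.transition_age,
                                              g["total_depth_cm"], res_age)
            trows.append(dict(reservoir=rec.reservoir, core_id=rec.core_id,
                              transition_age_y=tr.transition_age,
                              transition_depth_cm=depth))
        transitions = pd.DataFrame(trows)
        transitions.to_csv(out / "transition.csv", index=False)
        report["stages"]["transition"] = {"n_cores": len(transitions)}

    with _stage("integrate"):
        cfg = lifetime.LifetimeConfig(
            lifetime_years=config.lifetime.lifetime_years,
            deposition_interval_years=config.lifetime.deposition_interval_years)
        life = lifetime.integrate_all(fits, transitions, cfg)
        life.to_csv(out / "lifetime.csv", index=False)
        summary = lifetime.summarize_reservoir(
            transitions.merge(life[["core_id", "beyond_fraction"]],
                              on="core_id", how="left"))
        summary.to_csv(out / "reservoir_summary.csv", index=False)
        report["stages"]["integrate"] = {"n_cores": len(life)}
        report["reservoir_summary"] = summary.to_dict(orient="records")

    with _stage("fit_global"):
        usable = pooled[(pooled["gas"] == "ch4") & (~pooled["excluded"])]
        model = globalmodel.fit_global(usable)
        (out / "global_model.json").write_text(
            json.dumps(model.to_dict(), indent=2))
        report["stages"]["fit_global"] = {"n": model.n, "r2": model.r2,
                                          "s2": model.s2}

    report["warnings"] = caught
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
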