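"""Orchestration: generate → fit → normalize → allocate → analyze.

A run executes six stages — simulate (or load), validate, fit_aci,
normalize, allocate, stats — writing every intermediate table as CSV so
any stage can be re-run from its upstream files.  Outputs are byte-stable:
identical config and seed give identical files (floats are written at 6
significant digits; the manifest carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biochem, fvcb, season, stats, thermal

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs", "write_csv_stable"]

log = logging.getLogger("photocap")

_FLOAT_FMT = "%.6g"


def write_csv_stable(df: pd.DataFrame, path) -> None:
    """CSV with a fixed dialect: UTF-8, comma, '.' decimal, 6 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``curves`` is either the literal string ``"synthetic"`` (generate the
    season) or a path to a curves CSV; ``traits`` likewise (ignored when
    synthetic — the generator's truth table provides the traits).
    """

    out_dir: str = "results/run"
    curves: str = "synthetic"
    traits: str = "synthetic"
    seed: int = 0
    noise_sd: float = 0.3  # µmol m⁻² s⁻¹ instrument noise on A
    ci_ca_ratio: float = 0.7
    use_duplicate_380: bool = False
    trim_tpu: bool = False
    a_sat_mode: str = "first"
    kinetics: str = "bernacchi"
    trajectory: season.TraitTrajectoryConfig | None = None
    n_trees: int = 500
    doy_rise: tuple[int, int] = (92, 126)  # seasonal-change comparisons
    doy_fall: tuple[int, int] = (126, 147)

    def resolved_trajectory(self) -> season.TraitTrajectoryConfig:
        cfg = self.trajectory or season.TraitTrajectoryConfig()
        cfg.rng_seed = self.seed
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        traj = raw.pop("trajectory", None)
        cfg = cls(**raw)
        if traj is not None:
            anchors = {
                k: season.TraitAnchors(**v) for k, v in traj.pop("anchors", {}).items()
            }
            base = season.TraitTrajectoryConfig()
            if anchors:
                merged = dict(base.anchors)
                merged.update(anchors)
                traj["anchors"] = merged
            cfg.trajectory = dataclasses.replace(base, **traj)
        return cfg


@dataclass
class RunManifest:
    """What a run did: config echo, per-stage record counts, warnings."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    version: str = "0.1.0"

    def add_stage(self, name: str, n_records: int, **extra) -> None:
        self.stages.append({"stage": name, "n_records": int(n_records), **extra})

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def validate_inputs(
    curves: list[fvcb.ACiCurve], samples: pd.DataFrame | None
) -> list[str]:
    """Invariant check of curve and trait records; report-only, no mutation."""
    violations: list[str] = []
    for c in curves:
        violations.extend(c.validate())
    if samples is not None:
        for _, row in samples.iterrows():
            m_a = 1.0e4 / row["sla_cm2_g"]
            rec = biochem.LeafSample(
                leaf_id=str(row["leaf_id"]),
                doy=int(row["doy"]),
                stage=str(row.get("stage", "")),
                n_area=float(row["n_area_ug_cm2"]),
                chl_area=float(row["chl_area_ug_cm2"]),
                car_area=float(row["car_area_ug_cm2"]),
                sla=float(row["sla_cm2_g"]),
                m_a=float(row["m_a_g_m2"]) if "m_a_g_m2" in row else m_a,
                n_mass=float(row["n_mass_g_g"])
                if "n_mass_g_g" in row
                else float(row["n_area_ug_cm2"]) / (100.0 * m_a),
            )
            violations.extend(rec.validate())
    return violations


def _fit_stage(curves, options):
    fits, failed = [], []
    for c in curves:
        fit = fvcb.fit_aci(c, options=options)
        fits.append(fit)
        if not fit.converged:
            failed.append(c.leaf_id)
    return fits, failed


def _samples_table(traits: pd.DataFrame, fits25: pd.DataFrame, a_sat: pd.DataFrame) -> pd.DataFrame:
    df = traits.merge(fits25[["leaf_id", "vcmax25", "jmax25"]], on="leaf_id")
    df = df.merge(a_sat, on="leaf_id", how="left")
    df["m_a_g_m2"] = 1.0e4 / df["sla_cm2_g"]
    df["n_mass_g_g"] = df["n_area_ug_cm2"] / (100.0 * df["m_a_g_m2"])
    df["n_area_g_m2"] = df["n_area_ug_cm2"] / 100.0
    fracs = [
        biochem.allocation_fractions(
            vcmax=row.vcmax25,
            jmax=row.jmax25,
            chl_area=row.chl_area_ug_cm2,
            m_a=row.m_a_g_m2,
            n_mass=row.n_mass_g_g,
            leaf_id=row.leaf_id,
        )
        for row in df.itertuples()
    ]
    df["p_r"] = [f.p_r for f in fracs]
    df["p_b"] = [f.p_b for f in fracs]
    df["p_l"] = [f.p_l for f in fracs]
    df["chl_to_n"] = df["chl_area_ug_cm2"] / df["n_area_ug_cm2"]
    return df


def _models_table(models: list[stats.RegressionModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        rows.append(
            {
                "response": m.response,
                "predictors": "+".join(m.predictors),
                "n": m.n,
                "r_squared": m.r_squared,
                "anova_f": m.anova_f,
                "anova_p": float(f"{m.anova_p:.3g}"),
                "stars": stats.significance_stars(m.anova_p),
                "intercept": m.coefficients["intercept"],
                **{f"coef_{p}": m.coefficients[p] for p in m.predictors},
                "units": ";".join(f"{k}={v}" for k, v in m.units.items()),
            }
        )
    return pd.DataFrame(rows)


def _seasonal_table(summaries: list[stats.SeasonalSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for t, ch in s.changes.items():
            rows.append(
                {
                    "trait": t,
                    "doy_from": s.doy_from,
                    "doy_to": s.doy_to,
                    "mean_from": ch.mean_from,
                    "mean_to": ch.mean_to,
                    "pct_rel_earlier": ch.pct_rel_earlier,
                    "pct_rel_later": ch.pct_rel_later,
                    "peak_doy": ch.peak_doy,
                    "peak_value": ch.peak_value,
                }
            )
    return pd.DataFrame(rows)


STAT_COLUMNS = [
    "vcmax25",
    "jmax25",
    "a_sat",
    "n_area_ug_cm2",
    "chl_area_ug_cm2",
    "car_area_ug_cm2",
]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all six stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(config))
    design = season.build_default_design()

    # stage 1: simulate or load
    if config.curves == "synthetic":
        traj = config.resolved_trajectory()
        truths = season.simulate_season(design, traj)
        curves = season.simulate_curves(
            truths, noise_sd=config.noise_sd, seed=config.seed, ci_ca_ratio=config.ci_ca_ratio
        )
        truth_df = season.truths_to_frame(truths)
        curves_df = season.curves_to_frame(curves, design)
        write_csv_stable(curves_df, out / "curves.csv")
        write_csv_stable(truth_df, out / "truth.csv")
        traits_df = truth_df.drop(columns=["vcmax25", "jmax25", "rd25"])
    else:
        curves_path = Path(config.curves)
        if not curves_path.exists():
            raise FileNotFoundError(f"curves file not found: {curves_path}")
        curves = fvcb.read_curves_csv(curves_path)
        traits_path = Path(config.traits)
        if not traits_path.exists():
            raise FileNotFoundError(f"traits file not found: {traits_path}")
        traits_df = pd.read_csv(traits_path)
    manifest.add_stage("simulate", len(curves), n_leaves=len(curves))
    log.info("simulate: %d curves", len(curves))

    # stage 2: validate (report-only)
    violations = validate_inputs(curves, traits_df)
    manifest.add_stage("validate", len(violations))
    manifest.warnings.extend(violations)
    log.info("validate: %d violations", len(violations))

    # stage 3: fit A/Ci curves
    options = fvcb.FitOptions(
        use_duplicate_380=config.use_duplicate_380, trim_tpu=config.trim_tpu
    )
    fits, failed = _fit_stage(curves, options)
    if failed:
        manifest.warnings.append(f"non-converged fits: {failed}")
    fits_df = fvcb.write_fits_csv(fits, out / "fits.csv")
    manifest.add_stage("fit_aci", len(fits), n_nonconverged=len(failed))
    log.info("fit_aci: %d fits, %d non-converged", len(fits), len(failed))

    # stage 4: normalize to 25°C
    fits_df = fits_df.copy()
    fits_df["vcmax25"] = [
        thermal.normalize_to_25(f.vcmax, f.leaf_temperature, thermal.VCMAX_ARRHENIUS)
        for f in fits
    ]
    fits_df["jmax25"] = [
        thermal.normalize_to_25(f.jmax, f.leaf_temperature, thermal.JMAX_ARRHENIUS)
        for f in fits
    ]
    write_csv_stable(fits_df, out / "fits25.csv")
    manifest.add_stage("normalize", len(fits_df))
    log.info("normalize: %d records", len(fits_df))

    # stage 5: allocation + merged sample table
    a_sat = pd.DataFrame(
        {
            "leaf_id": [c.leaf_id for c in curves],
            "a_sat": [fvcb.a_sat_from_curve(c, config.a_sat_mode) for c in curves],
        }
    )
    samples = _samples_table(traits_df, fits_df, a_sat)
    write_csv_stable(samples, out / "samples.csv")
    manifest.add_stage("allocate", len(samples))
    log.info("allocate: %d samples", len(samples))

    # stage 6: statistics
    rmat, _ = stats.correlation_matrix(samples, STAT_COLUMNS)
    write_csv_stable(rmat.reset_index(names="variable"), out / "correlations.csv")
    models = stats.model_suite(samples)
    write_csv_stable(_models_table(models), out / "models.csv")
    importance = stats.rf_importance(
        samples, settings=stats.RFSettings(n_trees=config.n_trees, seed=config.seed)
    )
    imp_df = pd.DataFrame(
        {
            "predictor": list(importance.inc_mse),
            "inc_mse_pct": list(importance.inc_mse.values()),
            "oob_mse": importance.oob_mse,
            "n_trees": config.n_trees,
            "seed": config.seed,
        }
    )
    write_csv_stable(imp_df, out / "importance.csv")
    summaries = [
        stats.seasonal_changes(samples, *config.doy_rise, traits=STAT_COLUMNS),
        stats.seasonal_changes(samples, *config.doy_fall, traits=STAT_COLUMNS),
    ]
    write_csv_stable(_seasonal_table(summaries), out / "seasonal.csv")
    manifest.add_stage("stats", len(models) + len(imp_df) + 2)
    log.info("stats: %d models", len(models))

    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    traj = echo.get("trajectory")
    if traj is not None and isinstance(traj.get("coupling"), np.ndarray):
        traj["coupling"] = traj["coupling"].tolist()
    return echo
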