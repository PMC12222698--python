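"""Pipeline orchestration: configuration, validation, and the report bundle.

``run_pipeline`` executes the stages in order — descriptive summaries,
annual indoor projection, deterministic risk, Monte Carlo risk with
sensitivity analysis, spirometry classification — writing per-stage CSV
artifacts plus one consolidated JSON bundle.  Rerunning with the same
configuration and seed reproduces the bundle bit-for-bit apart from the
timestamp in the provenance block.

Inputs may be paths to the canonical CSV schemas; any input left unset is
generated by :mod:`indoair.synthetic_data` from the run seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import deterministic_risk as det
from . import exposure_stats as es
from . import probabilistic_risk as prob
from . import spirometry as spiro
from . import synthetic_data as synth

SCHEMA_VERSION = "1"

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_RUNTIME_ERROR = 4


class ConfigError(ValueError):
    """A configuration problem (missing file, bad key, invalid value)."""


class DataValidationError(ValueError):
    """Input data violating the schema or a physical invariant."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for one pipeline run; YAML-loadable.

    ``annual_ambient_ug_m3`` supplies the one-year ambient means (C1) used by
    the annual indoor projection; the defaults are calibrated so that the
    default synthetic campaign projects to annual hazard quotients near 0.99
    (PM10) and 0.74 (PM2.5) against the CPCB annual limits.
    """

    seed: int = 0
    output_dir: str = "indoair-output"
    concentration_csv: str | None = None
    spectrum_csv: str | None = None
    spirometry_csv: str | None = None
    run_spirometry: bool = True
    annual_ambient_ug_m3: dict = field(
        default_factory=lambda: {"PM10": 183.0, "PM2.5": 98.6}
    )
    bc_fine_fraction: float = det.BC_FINE_FRACTION
    slope_factor: float = det.DEFAULT_SLOPE_FACTOR
    mc_iterations: int = 50_000
    equation_set: str = "ECSC-1993"
    histogram_bins: int = 10
    n_synthetic_steps: int = 4800
    n_synthetic_subjects: int = 184

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError as e:
            raise ConfigError(str(e)) from e
        except yaml.YAMLError as e:
            raise ConfigError(f"malformed config: {e}") from e
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results land does not affect them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_inputs(
    concentration_csv: str | None = None, spirometry_csv: str | None = None
) -> dict[str, list[str]]:
    """Validate input CSVs against schema and physical invariants.

    Returns ``{"errors": [...], "warnings": [...]}``; an unreadable file is
    an error, as are negative concentrations, non-monotone timestamps,
    FEV1 > FVC rows and out-of-range demographics.
    """
    errors: list[str] = []
    warnings: list[str] = []
    if concentration_csv is not None:
        try:
            df = pd.read_csv(concentration_csv, parse_dates=["timestamp"])
        except Exception as e:
            errors.append(f"concentration: unreadable ({e})")
            df = None
        if df is not None:
            required = {"timestamp", "site_id", "environment", "pollutant", "value_ug_m3"}
            missing = required - set(df.columns)
            if missing:
                errors.append(f"concentration: missing columns {sorted(missing)}")
            else:
                neg = df.index[df["value_ug_m3"] < 0]
                for i in neg[:10]:
                    errors.append(f"concentration: negative value at row {i}")
                bad_env = set(df["environment"]) - {"indoor", "outdoor"}
                if bad_env:
                    errors.append(f"concentration: unknown environment {sorted(bad_env)}")
                for key, grp in df.groupby(["site_id", "environment", "pollutant"]):
                    ts = pd.DatetimeIndex(grp.sort_values("timestamp")["timestamp"])
                    if len(ts) != len(ts.unique()):
                        errors.append(f"concentration: duplicate timestamps in series {key}")
    if spirometry_csv is not None:
        try:
            df = pd.read_csv(spirometry_csv)
        except Exception as e:
            errors.append(f"spirometry: unreadable ({e})")
            df = None
        if df is not None:
            missing = set(spiro._CSV_COLUMNS) - set(df.columns)
            if missing:
                errors.append(f"spirometry: missing columns {sorted(missing)}")
            else:
                for i, row in df.iterrows():
                    for k in (1, 2, 3):
                        fvc, fev1 = row[f"fvc{k}"], row[f"fev1_{k}"]
                        if pd.notna(fvc) and pd.notna(fev1) and fev1 > fvc:
                            errors.append(
                                f"spirometry: FEV1 > FVC at row {i} manoeuvre {k} "
                                "(violates the session invariant 0 < FEV1 <= FVC)"
                            )
                    if pd.notna(row["age_y"]) and not (15 <= row["age_y"] <= 80):
                        warnings.append(f"spirometry: age out of range at row {i}")
    return {"errors": errors, "warnings": warnings}


def _series_key(s: es.ConcentrationSeries) -> str:
    return f"{s.environment.value}:{s.pollutant}"


def _load_or_generate_inputs(cfg: RunConfig):
    if cfg.concentration_csv is not None:
        series = {
            _series_key(s): s for s in es.read_concentration_csv(cfg.concentration_csv)
        }
        spectrum = (
            es.read_spectrum_csv(cfg.spectrum_csv) if cfg.spectrum_csv else None
        )
    else:
        model = synth.ConcentrationModel(n_steps=cfg.n_synthetic_steps)
        series, spectrum = synth.generate_concentrations(
            model, seed=cfg.seed, with_spectrum=True
        )
    sessions = truth = None
    if cfg.run_spirometry:
        if cfg.spirometry_csv is not None:
            sessions = spiro.read_spirometry_csv(cfg.spirometry_csv)
        else:
            sessions, truth = synth.generate_cohort(
                synth.CohortModel(n_subjects=cfg.n_synthetic_subjects), seed=cfg.seed
            )
    return series, spectrum, sessions, truth


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage and return the report bundle (also written to disk).

    Raises :class:`StageError` naming the failing stage; artifacts from
    completed stages are retained in ``cfg.output_dir``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
        },
        "units": {
            "concentration": "ug/m3",
            "CDI": "mg/kg/day",
            "RfD": "mg/kg/day",
            "HQ": "dimensionless",
            "LCR": "dimensionless",
            "spirometry_volumes": "L",
            "PEFR": "L/s",
        },
    }

    try:
        series, spectrum, sessions, truth = _load_or_generate_inputs(cfg)
    except (ConfigError, FileNotFoundError) as e:
        raise StageError("inputs", e)

    # --- stage 1: descriptive summaries -----------------------------------
    try:
        summaries = {k: es.summarize(s, cfg.histogram_bins) for k, s in series.items()}
        summary_df = pd.DataFrame(
            {k: v.as_dict() for k, v in summaries.items()}
        ).T.rename_axis("series")
        summary_df.to_csv(out / "summaries.csv")
        corr_pairs = [
            ("indoor:PM10", "indoor:PM2.5"),
            ("outdoor:PM10", "outdoor:PM2.5"),
            ("indoor:PM2.5", "indoor:BC"),
            ("indoor:BC", "outdoor:BC"),
        ]
        corr_rows = []
        for a, b in corr_pairs:
            if a in series and b in series:
                r = es.pearson(series[a].values, series[b].values)
                corr_rows.append({"a": a, "b": b, "r": r.r, "p_value": r.p_value, "n": r.n})
        corr_df = pd.DataFrame(corr_rows)
        corr_df.to_csv(out / "correlations.csv", index=False)
        io_rows = []
        for pol in ("PM10", "PM2.5", "PM1", "BC"):
            ki, ko = f"indoor:{pol}", f"outdoor:{pol}"
            if ki in summaries and ko in summaries:
                ratio, excess = es.io_ratio(summaries[ki], summaries[ko])
                io_rows.append({"pollutant": pol, "io_ratio": ratio, "percent_excess": excess})
        io_df = pd.DataFrame(io_rows)
        io_df.to_csv(out / "io_ratios.csv", index=False)
        shapes = {}
        for k, s in series.items():
            try:
                shapes[k] = es.distribution_shape(s).selected
            except ValueError:
                shapes[k] = "indeterminate"
        bundle["exposure"] = {
            "summaries": summary_df.reset_index().to_dict(orient="records"),
            "correlations": corr_rows,
            "io_ratios": io_rows,
            "distribution_shapes": shapes,
        }
        if spectrum is not None and "indoor:BC" in series:
            bin_corr = es.size_resolved_correlation(spectrum, series["indoor:BC"])
            bin_corr.to_csv(out / "size_resolved_correlation.csv", index=False)
            bundle["exposure"]["size_resolved_top_bins"] = (
                bin_corr.nlargest(5, "r_mass")["bin_low_um"].tolist()
            )
    except Exception as e:
        raise StageError("summaries", e)

    # --- stage 2: annual indoor projection ---------------------------------
    try:
        projections = {}
        for pol, c1 in cfg.annual_ambient_ug_m3.items():
            ki, ko = f"indoor:{pol}", f"outdoor:{pol}"
            if ki in summaries and ko in summaries:
                p = es.ProjectionInputs(c1, summaries[ki].mean, summaries[ko].mean)
                projections[pol] = es.annual_projection(p)
        bundle["annual_projection_ug_m3"] = projections
    except Exception as e:
        raise StageError("projection", e)

    # --- stage 3: deterministic risk ---------------------------------------
    try:
        ca_study = {
            pol: det.ug_to_mg_per_m3(summaries[f"indoor:{pol}"].mean)
            for pol in ("PM10", "PM2.5", "BC")
            if f"indoor:{pol}" in summaries
        }
        bc_fine = ca_study.get("BC", 0.0) * cfg.bc_fine_fraction
        guidelines_24h = {
            "PM10": det.lookup_guideline("PM10", "CPCB", "24h"),
            "PM2.5": det.lookup_guideline("PM2.5", "CPCB", "24h"),
            "BC": det.lookup_guideline("BC", "OSHA_NIOSH", "8h"),
        }
        risk_study = det.cohort_risk_table(
            {k: v for k, v in ca_study.items()}, guidelines=guidelines_24h
        )
        risk_study.to_csv(out / "risk_deterministic_study_period.csv", index=False)
        lcr_table = det.cohort_risk_table(
            {"BC_fine": bc_fine}, slope_factors={"BC_fine": cfg.slope_factor}
        )
        lcr_table.to_csv(out / "risk_deterministic_lcr.csv", index=False)
        ca_annual = {
            pol: det.ug_to_mg_per_m3(c4) for pol, c4 in projections.items()
        }
        annual_rows = []
        for agency in ("CPCB", "WHO"):
            for pol, ca in ca_annual.items():
                g = det.lookup_guideline(pol, agency, "annual")
                c = det.DEFAULT_COHORTS[0]
                f = det.ExposureFactors(
                    ca, c.IR_daily, det.DEFAULT_ET, det.DEFAULT_EF,
                    det.DEFAULT_ED, c.BW, det.DEFAULT_ED,
                )
                annual_rows.append(
                    {"agency": agency, "pollutant": pol, "HQ": det.hazard_quotient(f, g, c)}
                )
        annual_hq = pd.DataFrame(annual_rows)
        annual_hq.to_csv(out / "risk_deterministic_annual_hq.csv", index=False)
        hq_bc = float(risk_study.loc[risk_study.pollutant == "BC", "HQ"].iloc[0]) if "BC" in ca_study else 0.0
        hi_annual = det.hazard_index(
            list(annual_hq.loc[annual_hq.agency == "CPCB", "HQ"]) + [hq_bc]
        )
        bundle["deterministic"] = {
            "study_period_hq": {
                row["pollutant"]: row["HQ"]
                for _, row in risk_study.drop_duplicates("pollutant").iterrows()
            },
            "annual_hq": annual_rows,
            "hazard_index_annual_cpcb": hi_annual,
            "hazard_index_class": det.classify_risk(hq=hi_annual),
            "lcr_by_cohort": lcr_table[["sex", "age_band", "LCR", "risk_class"]].to_dict(
                orient="records"
            ),
        }
    except Exception as e:
        raise StageError("deterministic_risk", e)

    # --- stage 4: probabilistic risk + sensitivity -------------------------
    try:
        cfg_mc = prob.MCConfig(n_iterations=cfg.mc_iterations, seed=cfg.seed)
        mc_rows = []
        sens_lcr = None
        for cohort in det.DEFAULT_COHORTS:
            ca_sd = det.ug_to_mg_per_m3(
                summaries["indoor:BC"].sd * cfg.bc_fine_fraction
            ) if "indoor:BC" in summaries else 0.0
            specs = prob.default_specs(bc_fine, max(ca_sd, 1e-12), cohort)
            mc = prob.run_monte_carlo(specs, cfg_mc, "LCR", slope_factor=cfg.slope_factor)
            det_lcr = float(
                lcr_table.loc[
                    (lcr_table.sex == cohort.sex) & (lcr_table.age_band == cohort.age_band),
                    "LCR",
                ].iloc[0]
            )
            mc_rows.append(
                {
                    "sex": cohort.sex,
                    "age_band": cohort.age_band,
                    "deterministic_LCR": det_lcr,
                    "probabilistic_LCR_mean": mc.mean,
                    "LCR_p5": mc.percentiles["p5"],
                    "LCR_p95": mc.percentiles["p95"],
                    "percent_difference": prob.percent_difference(det_lcr, mc.mean),
                    "P_LCR_gt_1e4": mc.exceedance,
                }
            )
            if sens_lcr is None:
                sens_lcr = prob.sensitivity_analysis(
                    specs, cfg_mc, "LCR", slope_factor=cfg.slope_factor
                )
        mc_df = pd.DataFrame(mc_rows)
        mc_df.to_csv(out / "risk_probabilistic_lcr.csv", index=False)
        bundle["probabilistic"] = {
            "lcr_by_cohort": mc_rows,
            "sensitivity_lcr_percent": sens_lcr.contributions if sens_lcr else {},
            "n_iterations": cfg.mc_iterations,
        }
    except Exception as e:
        raise StageError("probabilistic_risk", e)

    # --- stage 5: spirometry ------------------------------------------------
    if cfg.run_spirometry:
        try:
            table = spiro.classification_table(sessions, cfg.equation_set)
            table.to_csv(out / "spirometry_classification.csv", index=False)
            classes = [
                spiro.classify_session(s, cfg.equation_set) for s in sessions
            ]
            prevalence = spiro.cohort_prevalence(classes)
            prevalence.to_csv(out / "spirometry_prevalence.csv", index=False)
            bundle["spirometry"] = {
                "prevalence": prevalence.to_dict(orient="records"),
                "n_sessions": len(sessions),
            }
            if truth is not None:
                q = synth.generate_questionnaire(truth, seed=cfg.seed)
                qc = spiro.questionnaire_correlations(
                    q.drop(columns=["subject_id"]), tail="one"
                )
                qc.to_csv(out / "questionnaire_correlations.csv", index=False)
        except Exception as e:
            raise StageError("spirometry", e)

    (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
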