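"""End-to-end pipeline: simulate/load → threshold → fit → attribute → project.

A single :class:`RunConfig` drives the whole analysis. One global seed is
split deterministically into per-stage seeds, so the full run is a pure
function of (inputs, config). Every stage writes plain CSV/JSON artifacts
and the run closes with a manifest recording parameters, derived seeds,
library versions and a SHA-256 checksum of each output file — two runs of
the same config produce bit-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import attribute_period
from .basis import CrossBasisSpec, build_crossbasis, predict_cumulative, predict_lag_response
from .errors import InvalidConfigError
from .io import model_to_json, read_daily_csv, write_daily_csv
from .projection import SSP_SCENARIOS, Scenario, format_table, project_burden, scenario_table
from .regression import build_design, find_mmt, fit_quasipoisson
from .series import DailySeries
from .synthetic import SimConfig, TrueSurface, simulate_counts, simulate_weather
from .threshold import aggregate_by_temperature, default_grid, fit_segmented, join_point_report

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "threshold", "fit", "attribution", "projection")


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults."""

    input: str | None = None  # CSV path; None -> simulate
    outdir: str = "heatdlnm_out"
    # simulation (used when input is None)
    n_years: int = 10
    # threshold stage
    bin_width: float = 1.0
    grid_step: float = 0.5
    threshold_mode: str = "continuous"
    # model stage
    lag_max: int = 7
    df_var: int = 5
    df_lag: int = 4
    df_doy: int = 4
    df_time: int = 3
    # attribution / projection
    n_sim: int = 1000
    scenarios: list[dict] = field(default_factory=list)
    sample_delta: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.bin_width <= 0 or self.grid_step <= 0:
            raise InvalidConfigError("bin_width and grid_step must be positive")
        if self.lag_max < 0 or self.df_var < 2 or self.df_lag < 1:
            raise InvalidConfigError("need lag_max >= 0, df_var >= 2, df_lag >= 1")
        if self.df_lag > self.lag_max + 1:
            raise InvalidConfigError("df_lag cannot exceed lag_max + 1")
        if self.df_doy < 2 or self.df_time < 2:
            raise InvalidConfigError("confounder splines need df >= 2")
        if self.n_sim < 0:
            raise InvalidConfigError("n_sim must be >= 0")
        if self.n_years < 1:
            raise InvalidConfigError("n_years must be >= 1")
        if self.threshold_mode not in ("continuous", "free"):
            raise InvalidConfigError(f"unknown threshold mode {self.threshold_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for name, child in zip(_STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scenarios_from_config(config: RunConfig) -> list[Scenario]:
    if not config.scenarios:
        return list(SSP_SCENARIOS)
    out = []
    for s in config.scenarios:
        out.append(
            Scenario(
                name=s["name"],
                delta_mean=float(s["delta_mean"]),
                delta_ci=tuple(s.get("delta_ci", (s["delta_mean"], s["delta_mean"]))),
                period=s.get("period", "2090-2099"),
            )
        )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the manifest.

    Stage errors abort the run; the manifest written up to that point
    (``manifest.partial.json``) names the failing stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "versions": _library_versions(),
        "config": asdict(config),
        "stage_seeds": seeds,
        "stages": {},
        "outputs": {},
    }
    current = "setup"
    try:
        # --- input -----------------------------------------------------
        current = "simulate"
        if config.input is None:
            sim = SimConfig(n_years=config.n_years, seed=seeds["simulate"])
            surface = TrueSurface()
            series = simulate_counts(simulate_weather(sim), surface, sim)
            data_path = outdir / "daily_series.csv"
            write_daily_csv(series, data_path)
            manifest["stages"]["simulate"] = {
                "n_days": len(series),
                "true_threshold": surface.threshold,
                "true_log_rr_per_degree": surface.log_rr_per_degree,
            }
            manifest["outputs"]["daily_series.csv"] = None  # checksum later
        else:
            series = read_daily_csv(config.input)
            manifest["stages"]["simulate"] = {"input": str(config.input), "n_days": len(series)}

        # --- threshold -------------------------------------------------
        current = "threshold"
        x, y, w = aggregate_by_temperature(series, config.bin_width)
        grid = default_grid(series.tmean, step=config.grid_step)
        seg = fit_segmented(x, y, w, grid, continuity_mode=config.threshold_mode)
        report = join_point_report(seg)
        (outdir / "threshold.json").write_text(json.dumps(report, indent=1))
        manifest["stages"]["threshold"] = {
            "tau": seg.tau,
            "segmented_preferred": report["segmented_preferred"],
        }

        # --- fit -------------------------------------------------------
        current = "fit"
        spec = CrossBasisSpec(
            lag_max=config.lag_max, df_var=config.df_var, df_lag=config.df_lag
        )
        cb = build_crossbasis(series.tmean, spec)
        design = build_design(series, cb, df_doy=config.df_doy, df_time=config.df_time)
        fit = fit_quasipoisson(design, cb)
        mmt = find_mmt(fit)
        model_to_json(fit, outdir / "model.json")
        curve = predict_cumulative(
            fit, cb, np.round(np.arange(series.tmean.min(), series.tmean.max() + 0.05, 0.1), 6), mmt
        )
        curve.to_frame().to_csv(outdir / "cumulative_curve.csv", index=False)
        rr1 = predict_cumulative(fit, cb, [seg.tau + 1.0], reference=seg.tau)
        manifest["stages"]["fit"] = {
            "dispersion": fit.dispersion,
            "qaic": fit.qaic,
            "mmt": mmt,
            "rr_per_degree_above_threshold": float(np.exp(rr1.log_rr[0])),
            "n_used": fit.n_used,
        }

        # --- attribution -----------------------------------------------
        current = "attribution"
        period = f"{series.dates[0].year}-{series.dates[-1].year}"
        attr = attribute_period(
            fit, series, reference=mmt, threshold=seg.tau, period=period,
            n_sim=config.n_sim, seed=seeds["attribution"],
        )
        pd.DataFrame([vars(attr)]).to_csv(outdir / "attribution.csv", index=False)
        manifest["stages"]["attribution"] = {
            "an": attr.an, "af_pct": attr.af_pct, "days_exceeding": attr.days_exceeding,
        }

        # --- projection ------------------------------------------------
        current = "projection"
        scenarios = _scenarios_from_config(config)
        baseline = _last_decade(series)
        base_period = f"{baseline.dates[0].year}-{baseline.dates[-1].year}"
        rows = []
        for i, sc in enumerate(scenarios):
            null_sc = Scenario(sc.name, 0.0, (0.0, 0.0), period=base_period)
            rows.append(
                project_burden(
                    fit, baseline, null_sc, threshold=seg.tau, reference=mmt,
                    n_sim=config.n_sim, seed=seeds["projection"] + 2 * i,
                    sample_delta=False,
                )
            )
            rows.append(
                project_burden(
                    fit, baseline, sc, threshold=seg.tau, reference=mmt,
                    n_sim=config.n_sim, seed=seeds["projection"] + 2 * i + 1,
                    sample_delta=config.sample_delta,
                )
            )
        table = scenario_table(rows)
        table.to_csv(outdir / "projection.csv", index=False)
        (outdir / "projection.txt").write_text(format_table(table))
        manifest["stages"]["projection"] = {
            "scenarios": [sc.name for sc in scenarios],
            "baseline_period": base_period,
        }
    except Exception:
        manifest["failed_stage"] = current
        (outdir / "manifest.partial.json").write_text(json.dumps(manifest, indent=1))
        raise

    for name in ("daily_series.csv", "threshold.json", "model.json",
                 "cumulative_curve.csv", "attribution.csv", "projection.csv",
                 "projection.txt"):
        p = outdir / name
        if p.exists():
            manifest["outputs"][name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _last_decade(series: DailySeries) -> DailySeries:
    """Last 10 full calendar years of the series (or all of it if shorter)."""
    last_year = series.dates[-1].year
    if series.dates[-1] != pd.Timestamp(year=last_year, month=12, day=31):
        last_year -= 1
    first = max(series.dates[0].year, last_year - 9)
    try:
        return series.between(f"{first}-01-01", f"{last_year}-12-31")
    except Exception:
        return series


def _library_versions() -> dict[str, str]:
    import pandas
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }
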