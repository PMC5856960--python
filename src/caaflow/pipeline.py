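"""Config-driven orchestration: morph -> tune -> simulate -> shear metrics.

One circulation is tuned per cohort and its coronary flow waveform is applied
unchanged to every geometry, so all between-case differences in the report are
induced purely by aneurysm shape.  The report mirrors the virtual-cohort
table layout (case id, D_max, length, aspect ratio, TAWSS, low-WSS area
percentages) plus convergence/tuning diagnostics, and a trend summary gives
the rank correlation between aspect ratio and mean TAWSS within each
fixed-D_max group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import circulation, geometry, hemodynamics, synthetic
from .circulation import ClinicalTargets, TuningError

__all__ = ["RunConfig", "CohortResult", "run_case", "run_cohort", "load_config"]

log = logging.getLogger("caaflow")

REPORT_COLUMNS = [
    "case_id", "D_max_mm", "length_mm", "aspect_ratio",
    "TAWSS", "Area_wss4", "Area_wss1", "OSI_max", "residence_time_s",
    "tuning_residual_max", "lpn_converged",
]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Declarative description of one cohort run."""

    cohort: str = "table1"  # built-in cohort name or path to a cohort file
    targets_file: str | None = None  # optional key: value clinical-targets file
    seed: int = 0
    baseline_diameter_mm: float = synthetic.DEFAULT_BASELINE_DIAMETER_MM
    n_cycles: int = 40
    dt: float | None = None
    ss_tol: float = 3e-4
    tune_tol: float = 0.05
    thresholds: tuple[float, float] = (4.0, 1.0)
    out_dir: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        hi, lo = self.thresholds
        if not (hi > lo > 0):
            raise ConfigError("thresholds must be positive and strictly decreasing")
        if self.targets_file is not None and not Path(self.targets_file).exists():
            raise ConfigError(f"targets file not found: {self.targets_file}")
        if self.cohort != "table1" and not Path(self.cohort).exists():
            raise ConfigError(f"unknown cohort: {self.cohort!r}")


def load_config(path) -> RunConfig:
    """Read a RunConfig from a flat YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a flat mapping")
    if "thresholds" in data:
        data["thresholds"] = tuple(float(x) for x in data["thresholds"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def read_targets(path) -> ClinicalTargets:
    """Read clinical targets from a flat ``key: value`` text file (YAML dialect)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ClinicalTargets(**data)


def write_targets(targets: ClinicalTargets, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(targets), fh, sort_keys=True)


@dataclass
class CohortResult:
    report: pd.DataFrame
    trend: dict
    waveforms: circulation.WaveformSet
    params: circulation.LPNParameters
    tuning_residuals: dict[str, float]
    exit_code: int


def _build_cohort(config: RunConfig) -> synthetic.CohortSpec:
    if config.cohort == "table1":
        targets = read_targets(config.targets_file) if config.targets_file else None
        return synthetic.table1_cohort(
            baseline_diameter=config.baseline_diameter_mm,
            seed=config.seed,
            targets=targets,
        )
    raise ConfigError(f"unsupported cohort source: {config.cohort!r}")


def run_case(
    spec: geometry.AneurysmSpec,
    centerline: geometry.CenterlinePath,
    waveforms: circulation.WaveformSet,
    thresholds: tuple[float, float] = (4.0, 1.0),
) -> dict:
    """Morph one case and evaluate its shear metrics under the shared flow."""
    geom = geometry.morph_aneurysm(centerline, spec)
    field_ = hemodynamics.wss_field(
        geom, waveforms.time, waveforms["coronary_flow"]
    )
    metrics = hemodynamics.summarize(
        geom, field_, waveforms.time, waveforms["coronary_flow"], thresholds=thresholds
    )
    is_control = spec.case_id == synthetic.CONTROL_CASE_ID
    return {
        "case_id": spec.case_id,
        "D_max_mm": spec.d_max,
        "length_mm": spec.length,
        "aspect_ratio": np.nan if is_control else round(geometry.aspect_ratio(spec), 2),
        "TAWSS": metrics.tawss_mean,
        "Area_wss4": metrics.area_wss4,
        "Area_wss1": metrics.area_wss1,
        "OSI_max": metrics.osi_max,
        "residence_time_s": metrics.residence_time,
    }


def _trend_summary(report: pd.DataFrame) -> dict:
    """Rank correlation of aspect ratio vs TAWSS within fixed-D_max groups."""
    morphs = report.dropna(subset=["aspect_ratio"])
    groups = {}
    for dmax, grp in morphs.groupby("D_max_mm"):
        if len(grp) < 2:
            continue
        if grp["aspect_ratio"].nunique() < 2 or grp["TAWSS"].nunique() < 2:
            rho = float("nan")
        else:
            rho = float(spearmanr(grp["aspect_ratio"], grp["TAWSS"]).statistic)
        ordered = grp.sort_values("aspect_ratio")
        strict = bool(np.all(np.diff(ordered["TAWSS"].to_numpy()) < 0))
        groups[f"dmax_{dmax:g}mm"] = {
            "spearman_rho": rho,
            "strictly_decreasing": strict,
            "n_cases": int(len(grp)),
        }
    return groups


def run_cohort(config: RunConfig) -> CohortResult:
    """Execute the full cohort: tune once, simulate once, morph per case.

    Returns the report, the per-group trend summary, and an exit code
    (0: all converged, 2: LPN failed to reach periodic steady state or tuning
    exhausted its budget).
    """
    cohort = _build_cohort(config)
    targets = cohort.targets
    log.info("cohort=%s cases=%d seed=%d", config.cohort, len(cohort.specs), config.seed)

    exit_code = 0
    try:
        params = circulation.tune(targets, tol=config.tune_tol, ss_tol=config.ss_tol)
    except TuningError as exc:
        log.warning("stage=tune budget exhausted: %s", exc)
        raise
    wf = circulation.simulate(
        params, targets.heart_rate,
        n_cycles=config.n_cycles, dt=config.dt, ss_tol=config.ss_tol,
    )
    if not wf.converged:
        log.warning("stage=simulate periodic steady state not reached")
        exit_code = 2
    meas = circulation._measure(wf)
    residuals = circulation._residuals(meas, targets)

    records = []
    for spec in cohort.specs:
        log.info("stage=metrics case=%s", spec.case_id)
        rec = run_case(spec, cohort.centerline, wf, thresholds=config.thresholds)
        rec["tuning_residual_max"] = max(residuals.values())
        rec["lpn_converged"] = wf.converged
        records.append(rec)
    report = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)

    trend = _trend_summary(report) if wf.converged else {}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "cohort_report.csv")
        summary = {
            "trend": trend,
            "tuning_residuals": residuals,
            "lpn_converged": bool(wf.converged),
            "exit_code": exit_code,
            "seed": config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        waveform_table = pd.DataFrame({"time_s": wf.time, **wf.channels})
        waveform_table.to_csv(out / "waveforms.csv", index=False, float_format="%.9g")

    return CohortResult(
        report=report, trend=trend, waveforms=wf, params=params,
        tuning_residuals=residuals, exit_code=exit_code,
    )


def write_report(report: pd.DataFrame, path) -> None:
    """Write the cohort report with a stable column order and float format."""
    report.to_csv(path, index=False, float_format="%.6g", na_rep="NA")
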