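"""End-to-end pipeline: samples + doses + weather -> fits, compositions,
water budget and cohort summary.

Stages: per subject-period washout fit (slope-intercept), dilution space
(TBW), body composition, weather aggregation and water turnover, then
cohort summaries.  QC failures (low R^2, flagged samples) are recorded in
the run log and the run continues on the remaining subject-periods;
cross-reference failures (a sample block with no matching dose) abort with
row detail.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .budget import MeasurementPeriod, aggregate_weather, water_turnover
from .composition import DEFAULT_HYDRATION_RATIO, compose
from .kinetics import (
    DoseEvent,
    FlaggedSampleError,
    InsufficientDataError,
    dilution_space,
    fit_washout,
)
from .cohort import group_summary, subject_means
from .io import read_table, write_table

logger = logging.getLogger("deutwater")

__all__ = ["PipelineConfig", "PipelineResult", "analyze_tables", "run_pipeline"]


@dataclass
class PipelineConfig:
    samples_csv: str = "samples.csv"
    doses_csv: str = "doses.csv"
    weather_csv: str = "weather.csv"
    species_csv: str | None = None
    output_dir: str = "out"
    hydration_ratio: float = DEFAULT_HYDRATION_RATIO
    dose_rate: float = 0.04
    qc_r_squared_min: float = 0.99
    round_report: bool = True  # masses to kg, fat% to integer in the report
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML config; unknown keys warn."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            logger.warning("ignoring unknown config key(s): %s", sorted(unknown))
        return cls(**{k: v for k, v in raw.items() if k in known})


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    compositions: pd.DataFrame
    budget: pd.DataFrame
    summary: pd.DataFrame
    qc_exclusions: list[dict] = field(default_factory=list)


def _summary_frame(comp: pd.DataFrame) -> pd.DataFrame:
    """Per-subject means +/- SD over periods, reference-report style."""
    rows = []
    for sid, sub in comp.groupby("subject_id", sort=True):
        rows.append(
            {
                "subject_id": sid,
                "n_periods": len(sub),
                "body_mass_mean": sub["body_mass"].mean(),
                "body_mass_sd": sub["body_mass"].std(ddof=1),
                "tbw_mean": sub["tbw"].mean(),
                "tbw_sd": sub["tbw"].std(ddof=1),
                "ffm_mean": sub["ffm"].mean(),
                "ffm_sd": sub["ffm"].std(ddof=1),
                "fat_percent_mean": sub["fat_percent"].mean(),
                "fat_percent_sd": sub["fat_percent"].std(ddof=1),
                "water_turnover_mean": sub["water_turnover"].mean(),
                "water_turnover_sd": sub["water_turnover"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def analyze_tables(
    samples: pd.DataFrame,
    doses: pd.DataFrame,
    weather: pd.DataFrame,
    *,
    hydration_ratio: float = DEFAULT_HYDRATION_RATIO,
    qc_r_squared_min: float = 0.99,
) -> PipelineResult:
    """In-memory fit -> compose -> budget on the three input tables."""
    config = PipelineConfig(
        hydration_ratio=hydration_ratio, qc_r_squared_min=qc_r_squared_min
    )
    dose_index = {
        (r.subject_id, r.period_id): r for r in doses.itertuples(index=False)
    }
    missing_refs = []
    for i, (key, _) in enumerate(samples.groupby(["subject_id", "period_id"])):
        if key not in dose_index:
            missing_refs.append((i, key))
    if missing_refs:
        detail = "; ".join(f"block {i}: {k}" for i, k in missing_refs)
        raise ValueError(f"sample blocks without a matching dose: {detail}")

    fit_rows, comp_rows, budget_rows, exclusions = [], [], [], []
    for (sid, pid), block in samples.groupby(["subject_id", "period_id"], sort=True):
        dose_rec = dose_index[(sid, pid)]
        base = block[block["is_baseline"].astype(bool)]
        post = block[~block["is_baseline"].astype(bool)]
        if len(base) != 1:
            exclusions.append(
                {"subject_id": sid, "period_id": pid,
                 "reason": f"{len(base)} baseline samples (need exactly 1)"}
            )
            continue
        baseline = float(base["enrichment"].iloc[0])
        try:
            fit = fit_washout(
                post["time_since_dose"].to_numpy(float),
                post["enrichment"].to_numpy(float),
                baseline,
                qc_r_squared_min=config.qc_r_squared_min,
                subject_id=sid,
                period_id=pid,
            )
        except (FlaggedSampleError, InsufficientDataError) as err:
            exclusions.append({"subject_id": sid, "period_id": pid, "reason": str(err)})
            continue
        fit_rows.append(
            {
                "subject_id": sid,
                "period_id": pid,
                "e0_excess": fit.e0_excess,
                "kd": fit.kd,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "qc_pass": fit.qc_pass,
            }
        )
        if not fit.qc_pass:
            exclusions.append(
                {"subject_id": sid, "period_id": pid,
                 "reason": f"QC fail: R^2={fit.r_squared:.4f} < {config.qc_r_squared_min}"}
            )
            continue
        dose = DoseEvent(
            subject_id=sid,
            period_id=pid,
            dose_mass=float(dose_rec.dose_mass_g),
            purity=float(dose_rec.purity),
            body_mass_at_dose=float(dose_rec.body_mass_kg),
        )
        tbw = dilution_space(fit, dose, baseline)
        comp = compose(
            float(dose_rec.body_mass_kg),
            tbw,
            config.hydration_ratio,
            subject_id=sid,
            period_id=pid,
        )
        turnover = water_turnover(fit, tbw)
        agg = aggregate_weather(weather, pd.Timestamp(dose_rec.dose_time).normalize())
        comp_rows.append(
            {
                "subject_id": sid,
                "period_id": pid,
                "body_mass": comp.body_mass,
                "tbw": comp.tbw,
                "ffm": comp.ffm,
                "fat_mass": comp.fat_mass,
                "fat_percent": comp.fat_percent,
                "negative_fat_warning": comp.negative_fat_warning,
                "water_turnover": turnover,
            }
        )
        budget_rows.append(
            {
                "subject_id": sid,
                "period_id": pid,
                "water_turnover": turnover,
                "turnover_pct_tbw": 100.0 * turnover / tbw,
                **agg,
            }
        )
        if comp.negative_fat_warning:
            logger.warning("negative fat mass for %s/%s (%.1f kg)", sid, pid, comp.fat_mass)

    fits = pd.DataFrame(fit_rows)
    compositions = pd.DataFrame(comp_rows)
    budget = pd.DataFrame(budget_rows)
    summary = _summary_frame(compositions) if len(compositions) else pd.DataFrame()
    return PipelineResult(fits, compositions, budget, summary, exclusions)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute fit -> compose -> budget -> summaries and write outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = read_table(config.samples_csv, "samples")
    doses = read_table(config.doses_csv, "doses")
    weather = read_table(config.weather_csv, "weather")
    res = analyze_tables(
        samples,
        doses,
        weather,
        hydration_ratio=config.hydration_ratio,
        qc_r_squared_min=config.qc_r_squared_min,
    )
    fits, compositions, budget = res.fits, res.compositions, res.budget
    summary, exclusions = res.summary, res.qc_exclusions

    write_table(fits, out / "fits.csv", "fits")
    compositions.to_csv(out / "compositions.csv", index=False, float_format="%.10g")
    budget.to_csv(out / "budget.csv", index=False, float_format="%.10g")
    report = summary.copy()
    if config.round_report and len(report):
        for c in report.columns:
            if c.startswith(("body_mass", "tbw", "ffm", "water_turnover")) or c.startswith(
                "fat_percent"
            ):
                report[c] = report[c].round(0).astype("Int64")
    report.to_csv(out / "summary.csv", index=False)

    log_lines = [
        f"deutwater {__version__} on python {platform.python_version()}",
        f"seed {config.seed}; hydration_ratio {config.hydration_ratio}; "
        f"qc_r_squared_min {config.qc_r_squared_min}",
        f"{len(fits)} subject-periods fitted; {len(exclusions)} excluded:",
        *(f"  {e['subject_id']}/{e['period_id']}: {e['reason']}" for e in exclusions),
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    for e in exclusions:
        logger.info("excluded %s/%s: %s", e["subject_id"], e["period_id"], e["reason"])
    return PipelineResult(fits, compositions, budget, summary, exclusions)
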