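"""Shared fixtures: synthetic cohorts and the published reference cohort."""

from __future__ import annotations

import pandas as pd
import pytest

from deutwater.pipeline import analyze_tables
from deutwater.reference import reference_cohort
from deutwater.synthetic import SimulationConfig, generate_cohort


def turnover_frame(
    seed: int,
    n_subjects: int = 20,
    n_periods: int = 6,
    temp_coefficient: float = 0.02,
    noise_cv: float = 0.002,
) -> tuple[pd.DataFrame, SimulationConfig]:
    """Generate a cohort and run the full analysis to a per-period frame.

    Returns a frame with subject_id, body_mass, mean_temp, water_turnover
    (one row per subject-period) plus the config used.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_subjects=n_subjects,
        n_periods=n_periods,
        temp_coefficient=temp_coefficient,
        enrichment_noise_cv=noise_cv,
    )
    _, samples, doses, weather = generate_cohort(cfg)
    res = analyze_tables(samples, doses, weather)
    df = res.compositions.merge(
        res.budget[["subject_id", "period_id", "mean_temp"]],
        on=["subject_id", "period_id"],
    )
    return df[["subject_id", "period_id", "body_mass", "tbw", "water_turnover", "mean_temp"]], cfg


@pytest.fixture(scope="session")
def reference():
    """Per-subject study means for the five-elephant reference cohort."""
    return reference_cohort()


@pytest.fixture(scope="session")
def noisefree_cohort():
    """A five-subject cohort with zero noise, jittered times, no temp effect."""
    cfg = SimulationConfig(seed=11, enrichment_noise_cv=0.0, temp_coefficient=0.0)
    truths, samples, doses, weather = generate_cohort(cfg)
    return cfg, truths, samples, doses, weather
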