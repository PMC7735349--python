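"""Isotope washout kinetics and dilution-space estimation.

The slope-intercept method regresses the natural log of excess deuterium
enrichment (sample enrichment minus the pre-dose baseline) on time since
dose.  The negated slope is the depletion rate constant ``kd`` (d^-1) and
the exponentiated intercept is the back-extrapolated initial excess
enrichment ``e0_excess`` at dose time.  Total body water then follows from
an exact mass balance: the deuterium atoms in the dose, mixed into the body
water pool at the baseline isotopic composition, must produce exactly that
initial excess.

Enrichments are expressed throughout as ppm of deuterium in total hydrogen
(atom fraction x 1e6); a VSMOW-like natural background is roughly 155.76
ppm.  Any linear enrichment unit works as long as the dose purity, baseline
and fitted excess use the same unit and the matching ``atom_fraction_per_unit``
conversion is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MM_H2O",
    "MM_D2O",
    "WATER_DENSITY_KG_PER_L",
    "DoseEvent",
    "WashoutFit",
    "FlaggedSampleError",
    "InsufficientDataError",
    "fit_washout",
    "dilution_space",
    "mixing_excess_enrichment",
    "dose_for_mass",
]

#: molecular masses, g/mol
MM_H2O = 18.0153
MM_D2O = 20.0276
#: litres of body water are treated as kg of water
WATER_DENSITY_KG_PER_L = 1.000

#: ppm of total hydrogen -> atom fraction
PPM_TO_ATOM_FRACTION = 1e-6


class FlaggedSampleError(ValueError):
    """A post-dose sample at or below baseline enrichment.

    Signals an uningested or partial dose (or a mislabeled sample); the
    washout line cannot be fitted through it.
    """


class InsufficientDataError(ValueError):
    """Fewer than two usable post-dose samples."""


@dataclass(frozen=True)
class DoseEvent:
    """One labelled-water dose administered to a subject.

    Attributes
    ----------
    dose_mass : float
        Mass of labelled water given, grams.
    purity : float
        Fraction of dose molecules that are 2H2O (e.g. 0.998).
    body_mass_at_dose : float
        Scale mass at dosing, kg.
    """

    subject_id: str
    period_id: str
    dose_mass: float
    purity: float = 0.998
    dose_time: str | None = None
    body_mass_at_dose: float | None = None

    def __post_init__(self) -> None:
        if self.dose_mass <= 0:
            raise ValueError(f"dose_mass must be positive, got {self.dose_mass}")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


@dataclass(frozen=True)
class WashoutFit:
    """Fitted washout line for one subject-period.

    ``e0_excess`` is the back-extrapolated excess enrichment at dose time
    (same unit as the input enrichments), ``kd`` the depletion rate
    constant in d^-1.
    """

    e0_excess: float
    kd: float
    r_squared: float
    n_points: int
    qc_pass: bool
    subject_id: str = ""
    period_id: str = ""


def fit_washout(
    times: Sequence[float],
    enrichments: Sequence[float],
    baseline: float,
    *,
    qc_r_squared_min: float = 0.99,
    min_time: float = 0.0,
    subject_id: str = "",
    period_id: str = "",
) -> WashoutFit:
    """Fit ln(excess enrichment) against time since dose by OLS.

    Parameters
    ----------
    times : sequence of float
        Days since dose for each post-dose sample; must be positive and
        distinct.
    enrichments : sequence of float
        Measured enrichment at each time, same unit as ``baseline``; every
        value must exceed the baseline.
    baseline : float
        Pre-dose enrichment.
    qc_r_squared_min : float
        R^2 below this marks the fit ``qc_pass=False`` (reported, never
        silently dropped).
    min_time : float
        Samples earlier than this (days) are excluded — an equilibration
        guard.  Default 0 keeps everything.

    Returns
    -------
    WashoutFit
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(enrichments, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and enrichments must be 1-d and equal length")
    if np.any(t <= 0):
        raise ValueError("post-dose sample times must be strictly positive")
    keep = t >= min_time
    t, e = t[keep], e[keep]
    low = e <= baseline
    if np.any(low):
        bad = t[low]
        raise FlaggedSampleError(
            f"{low.sum()} post-dose sample(s) at or below baseline enrichment "
            f"(times {np.round(bad, 3).tolist()} d): possible uningested or "
            "partial dose"
        )
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 usable post-dose samples, have {t.size}"
        )
    if np.unique(t).size != t.size:
        raise ValueError("post-dose sample times must be distinct")

    ln_excess = np.log(e - baseline)
    res = stats.linregress(t, ln_excess)
    kd = -res.slope
    e0 = float(np.exp(res.intercept))
    r2 = float(res.rvalue**2) if t.size > 2 else 1.0 if np.isfinite(res.rvalue) else 0.0
    if t.size == 2:
        # two points define the line exactly
        r2 = 1.0
    qc = bool(r2 >= qc_r_squared_min and kd > 0 and e0 > 0)
    return WashoutFit(
        e0_excess=e0,
        kd=float(kd),
        r_squared=r2,
        n_points=int(t.size),
        qc_pass=qc,
        subject_id=subject_id,
        period_id=period_id,
    )


def _dose_hydrogen_moles(dose: DoseEvent) -> tuple[float, float]:
    """Moles of total H and of 2H delivered by the dose.

    The non-2H2O remainder of the dose is taken to be ordinary water.
    """
    mm_dose = dose.purity * MM_D2O + (1.0 - dose.purity) * MM_H2O
    mol_water = dose.dose_mass / mm_dose
    n_h_total = 2.0 * mol_water
    n_d = 2.0 * dose.purity * mol_water
    return n_h_total, n_d


def mixing_excess_enrichment(
    dose: DoseEvent,
    volume_l: float,
    baseline: float,
    *,
    atom_fraction_per_unit: float = PPM_TO_ATOM_FRACTION,
) -> float:
    """Forward mixing model: excess enrichment from dosing ``volume_l``.

    Exact mass balance of deuterium atoms: mixing the dose into a pool of
    ``volume_l`` litres of water at the baseline atom fraction yields the
    post-equilibration atom fraction; returned as excess enrichment above
    baseline, in the unit implied by ``atom_fraction_per_unit``.
    """
    if volume_l <= 0:
        raise ValueError(f"pool volume must be positive, got {volume_l}")
    x_base = baseline * atom_fraction_per_unit
    n_h_pool = 2.0 * (volume_l * WATER_DENSITY_KG_PER_L * 1000.0) / MM_H2O
    n_h_dose, n_d_dose = _dose_hydrogen_moles(dose)
    x_after = (x_base * n_h_pool + n_d_dose) / (n_h_pool + n_h_dose)
    return (x_after - x_base) / atom_fraction_per_unit


def dilution_space(
    fit: WashoutFit,
    dose: DoseEvent,
    baseline: float,
    *,
    atom_fraction_per_unit: float = PPM_TO_ATOM_FRACTION,
    require_qc: bool = True,
) -> float:
    """Invert the mixing mass balance: body-water volume in litres.

    Solves for the pool volume V such that ``mixing_excess_enrichment``
    applied to V reproduces ``fit.e0_excess`` exactly.  This is the total
    body water (including gut-content water) sampled by the tracer.
    """
    if require_qc and not fit.qc_pass:
        raise ValueError(
            f"washout fit for {fit.subject_id}/{fit.period_id} failed QC "
            f"(R^2={fit.r_squared:.4f}); pass require_qc=False to override"
        )
    if fit.e0_excess <= 0:
        raise ValueError("e0_excess must be positive")
    x_base = baseline * atom_fraction_per_unit
    dx = fit.e0_excess * atom_fraction_per_unit
    n_h_dose, n_d_dose = _dose_hydrogen_moles(dose)
    # dx = (n_d_dose - x_base * n_h_dose) / (n_h_pool + n_h_dose)
    n_h_pool = (n_d_dose - x_base * n_h_dose) / dx - n_h_dose
    if n_h_pool <= 0:
        raise ValueError(
            "mass balance gives a non-positive pool: dose too small or "
            "excess enrichment too large for this baseline"
        )
    grams = n_h_pool * MM_H2O / 2.0
    return grams / (1000.0 * WATER_DENSITY_KG_PER_L)


def dose_for_mass(body_mass: float, dose_rate: float = 0.04) -> float:
    """Dose of labelled water (g) for a subject: ``dose_rate`` g per kg."""
    if body_mass <= 0:
        raise ValueError(f"body_mass must be positive, got {body_mass}")
    if dose_rate <= 0:
        raise ValueError(f"dose_rate must be positive, got {dose_rate}")
    return dose_rate * body_mass
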