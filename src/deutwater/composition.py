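"""Body composition from total body water.

Fat-free mass (FFM, including fat-free gut content) is estimated from total
body water (TBW) with a hydration ratio, the TBW:FFM fraction of lean
tissue.  The default 0.746 is the cross-mammal mean; 0.730 is a common
alternative used in other elephant work.  Fat mass is body mass minus FFM.

Because gut contents are hydrated above the lean-tissue ratio (elephant gut
contents run 80-90% water against the assumed ~74.6%), isotope dilution
overestimates FFM and underestimates fat; `gut_fill_bias` quantifies that
from first principles.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DEFAULT_HYDRATION_RATIO",
    "ALTERNATE_HYDRATION_RATIO",
    "BodyComposition",
    "CompositionQCError",
    "compose",
    "hydration_sensitivity",
    "gut_fill_bias",
]

DEFAULT_HYDRATION_RATIO = 0.746
ALTERNATE_HYDRATION_RATIO = 0.730

#: fat percent below this signals a dosing/assay failure, not measurement noise
FAT_PERCENT_HARD_FLOOR = -5.0


class CompositionQCError(ValueError):
    """TBW grossly exceeds what the body mass can hold (fat% < -5)."""


@dataclass(frozen=True)
class BodyComposition:
    subject_id: str
    period_id: str
    body_mass: float  # kg
    tbw: float  # litres (= kg of water)
    hydration_ratio: float
    ffm: float  # kg, includes gut content
    fat_mass: float  # kg; may be slightly negative (measurement error)
    fat_percent: float  # % of body mass
    negative_fat_warning: bool


def compose(
    body_mass: float,
    tbw: float,
    hydration_ratio: float = DEFAULT_HYDRATION_RATIO,
    *,
    subject_id: str = "",
    period_id: str = "",
) -> BodyComposition:
    """FFM = TBW / hydration_ratio; fat = body mass - FFM.

    A mildly negative fat mass is retained and flagged (it is informative
    measurement error); fat percent below -5% raises
    :class:`CompositionQCError` as it indicates a failed dose or assay.
    """
    if body_mass <= 0:
        raise ValueError(f"body_mass must be positive, got {body_mass}")
    if tbw <= 0:
        raise ValueError(f"tbw must be positive, got {tbw}")
    if not 0 < hydration_ratio <= 1:
        raise ValueError(f"hydration_ratio must be in (0, 1], got {hydration_ratio}")
    ffm = tbw / hydration_ratio
    fat = body_mass - ffm
    fat_pct = 100.0 * fat / body_mass
    if fat_pct < FAT_PERCENT_HARD_FLOOR:
        raise CompositionQCError(
            f"fat percent {fat_pct:.1f}% < {FAT_PERCENT_HARD_FLOOR}% for "
            f"{subject_id}/{period_id}: TBW inconsistent with body mass "
            "(dosing or assay failure)"
        )
    return BodyComposition(
        subject_id=subject_id,
        period_id=period_id,
        body_mass=float(body_mass),
        tbw=float(tbw),
        hydration_ratio=float(hydration_ratio),
        ffm=float(ffm),
        fat_mass=float(fat),
        fat_percent=float(fat_pct),
        negative_fat_warning=bool(fat < 0),
    )


def hydration_sensitivity(
    body_mass: float,
    tbw: float,
    ratio_a: float = DEFAULT_HYDRATION_RATIO,
    ratio_b: float = ALTERNATE_HYDRATION_RATIO,
) -> float:
    """Change in body fat percent when moving from ratio_a to ratio_b.

    Returns fat_percent(ratio_a) - fat_percent(ratio_b) in percentage
    points, i.e. 100 * (tbw/body_mass) * (1/ratio_b - 1/ratio_a).  Positive
    when the switch a -> b reduces the reported fat percent (the usual case
    for ratio_b < ratio_a).
    """
    a = compose(body_mass, tbw, ratio_a)
    b = compose(body_mass, tbw, ratio_b)
    return a.fat_percent - b.fat_percent


def gut_fill_bias(
    body_mass: float,
    gut_fraction: float,
    gut_hydration: float,
    hydration_ratio: float = DEFAULT_HYDRATION_RATIO,
) -> float:
    """FFM overestimate (kg) from gut water hydrated above the lean ratio.

    Gut contents of mass ``body_mass * gut_fraction`` holding
    ``gut_hydration`` water contribute that water to TBW; dividing it by
    the lean ``hydration_ratio`` inflates FFM by

        body_mass * gut_fraction * (gut_hydration - hydration_ratio) / hydration_ratio

    kilograms.  Fat mass is underestimated by the same amount.
    """
    if not 0 <= gut_fraction < 1:
        raise ValueError(f"gut_fraction must be in [0, 1), got {gut_fraction}")
    if not 0 < gut_hydration <= 1:
        raise ValueError(f"gut_hydration must be in (0, 1], got {gut_hydration}")
    if body_mass <= 0:
        raise ValueError(f"body_mass must be positive, got {body_mass}")
    return body_mass * gut_fraction * (gut_hydration - hydration_ratio) / hydration_ratio
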