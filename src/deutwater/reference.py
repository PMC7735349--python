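"""Reference cohort: published summary values for five zoo-living African
elephants (two adult males, three females) measured by deuterium dilution
six times over three years.

Per-subject study means (with between-period SDs) of body mass, total body
water, fat-free mass (including gut content), body fat percent and daily
water turnover.  These printed values serve as a worked example and as a
cross-check fixture: FFM and fat percent must be recoverable from the
printed TBW and body mass with the 0.746 hydration ratio, and the group
summaries (male turnover 359 L/d; female 241 +/- 28 L/d) from the subject
means.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort", "REFERENCE_HYDRATION_RATIO"]

REFERENCE_HYDRATION_RATIO = 0.746

_ROWS = [
    # subject, sex, mass kg (sd), tbw L (sd), ffm kg (sd), fat % (sd), turnover L/d (sd)
    ("1770", "M", 5815, 190, 4020, 349, 5389, 467, 7, 6, 353, 43),
    ("27", "M", 5553, 107, 3698, 177, 4957, 238, 11, 4, 365, 97),
    ("1772", "F", 2654, 96, 1731, 79, 2320, 106, 13, 2, 227, 40),
    ("1611", "F", 4401, 140, 2817, 131, 3776, 175, 14, 2, 223, 42),
    ("1771", "F", 3905, 150, 2587, 142, 3467, 190, 11, 2, 273, 47),
]

_COLUMNS = [
    "subject_id",
    "sex",
    "body_mass",
    "body_mass_sd",
    "tbw",
    "tbw_sd",
    "ffm",
    "ffm_sd",
    "fat_percent",
    "fat_percent_sd",
    "water_turnover",
    "water_turnover_sd",
]


def reference_cohort() -> pd.DataFrame:
    """Per-subject study means for the five-elephant reference cohort."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
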