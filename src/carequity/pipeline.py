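"""From raw survey rows to the five-way utilization frequency table.

Respondent microdata (raw codes, visit counts) is categorized into the
five analysis axes — location, age band, SES tertile, GP visit and
specialist visit — and cross-tabulated into the dense table the
log-linear machinery consumes.
"""

from __future__ import annotations

import pandas as pd

from .ses import DEFAULT_BINNING, BinningMap, SesMetadata, assign_ses
from .tables import SURVEY_AXES, FrequencyTable, crosstab

__all__ = ["categorize_respondents", "utilization_table"]

_LOCATION_LABELS = {1: "peripheral", 2: "intermediate", 3: "central"}


def categorize_respondents(
    records: pd.DataFrame,
    binning: BinningMap = DEFAULT_BINNING,
    cutoffs: tuple[float, float] | None = None,
    elderly_age: float = 60.0,
) -> tuple[pd.DataFrame, SesMetadata]:
    """Categorize raw survey rows into the five analysis axes.

    Expects columns location (1-3), age (years), occupation, education,
    sec, rooms, gp_visits, sd_visits.  Returns the frame augmented with
    ses_score/ses_tertile plus label columns location, age, ses, vis_gp
    and vis_sd ready for :func:`utilization_table`, and the SES-run
    metadata (cutoffs, calibration, Cronbach's alpha, exclusions).
    """
    df, meta = assign_ses(records, binning=binning, cutoffs=cutoffs)
    bad_loc = ~df["location"].isin(_LOCATION_LABELS)
    if bad_loc.any():
        raise ValueError(
            f"row {df.index[bad_loc][0]}: location must be 1 (peripheral) .. 3 (central)"
        )
    out = df.copy()
    out["location"] = df["location"].map(_LOCATION_LABELS)
    out["age"] = (df["age"] >= elderly_age).map({True: "ge60", False: "lt60"})
    out["ses"] = out.pop("ses_tertile")
    out["vis_gp"] = (df["gp_visits"] > 0).map({True: "yes", False: "no"})
    out["vis_sd"] = (df["sd_visits"] > 0).map({True: "yes", False: "no"})
    return out, meta


def utilization_table(categorized: pd.DataFrame) -> FrequencyTable:
    """Cross-tabulate categorized respondents into the five-way table."""
    return crosstab(categorized, SURVEY_AXES)
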