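"""Cytometry and imaging quantification: spike-in normalization, pH ratio, LMP score.

Three small, exactly-specified formulas:

* relative ProteoStat = (sample treated / sample spike-in) divided by the
  same ratio for the negative-control sample — an internal-staining-control
  double normalization that cancels staining batch effects;
* the ratiometric lysosomal pH readout: background-subtracted sfGFP over
  background-subtracted mCherry, backgrounds taken from cognate non-reporter
  controls;
* the lysosomal membrane permeabilization (LMP) score: galectin-3 puncta per
  average-cell-area equivalent, averaged over fields per time point, with
  the sample's score being the maximum over the time course.

Event-level medians summarize intensity distributions throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "channel_medians",
    "proteostat_normalize",
    "phlare_ratio",
    "gal3_puncta_score",
]


def channel_medians(events: pd.DataFrame, channels: list[str] | None = None,
                    by: str = "population") -> pd.DataFrame:
    """Median intensity per population for each channel column."""
    if by not in events.columns:
        raise ValueError(f"missing grouping column {by!r}")
    if channels is None:
        channels = [c for c in events.columns
                    if c not in (by, "event_id") and
                    pd.api.types.is_numeric_dtype(events[c])]
    return events.groupby(by)[channels].median()


def proteostat_normalize(sample_treated: float, sample_spikein: float,
                         control_treated: float, control_spikein: float) -> float:
    """Double-normalized ProteoStat intensity.

    Each sample's treated-population median is first divided by its internal
    spike-in (untreated) control, then by the same ratio in the matched
    negative-control sample.  Scale-invariant in each sample's pair.
    """
    for name, v in (("sample_spikein", sample_spikein),
                    ("control_spikein", control_spikein)):
        if v <= 0:
            raise ValueError(f"{name} median must be positive")
    if min(sample_treated, control_treated) < 0:
        raise ValueError("medians must be non-negative")
    if control_treated == 0:
        raise ValueError("control treated median is zero")
    return (sample_treated / sample_spikein) / (control_treated / control_spikein)


def phlare_ratio(sfgfp_median: float, mcherry_median: float,
                 bg_sfgfp: float = 0.0, bg_mcherry: float = 0.0) -> float:
    """Background-corrected sfGFP/mCherry ratio of a ratiometric pH reporter.

    Backgrounds are channel medians of the cognate non-reporter control and
    must lie strictly below the reporter signal in both channels; no
    clamping is applied.
    """
    if bg_sfgfp >= sfgfp_median or bg_mcherry >= mcherry_median:
        raise ValueError("background >= signal; cannot form the ratio")
    return (sfgfp_median - bg_sfgfp) / (mcherry_median - bg_mcherry)


def gal3_puncta_score(fields: pd.DataFrame) -> tuple[pd.Series, float]:
    """LMP score from galectin-3 puncta counts per imaging field.

    Each field's count is normalized by ``total_cell_area / mean_cell_area``
    — the field's cell content in average-cell equivalents — correcting for
    cell density.  Fields are averaged within each time point and the
    reported sample score is the maximum over the time course.

    Parameters
    ----------
    fields
        Columns ``time_h, puncta, total_area, mean_cell_area`` (one row per
        field of view).

    Returns
    -------
    (per_time, score)
        Mean puncta-per-cell-equivalent per time point, and its maximum.
    """
    required = ("time_h", "puncta", "total_area", "mean_cell_area")
    missing = [c for c in required if c not in fields.columns]
    if missing:
        raise ValueError(f"puncta table missing columns: {missing}")
    if len(fields) == 0:
        raise ValueError("no fields provided")
    if (fields["total_area"] <= 0).any() or (fields["mean_cell_area"] <= 0).any():
        raise ValueError("cell areas must be positive")
    if (fields["puncta"] < 0).any():
        raise ValueError("puncta counts must be non-negative")
    per_field = fields["puncta"] / (fields["total_area"] / fields["mean_cell_area"])
    per_time = per_field.groupby(fields["time_h"]).mean().sort_index()
    per_time.name = "puncta_per_cell_equivalent"
    return per_time, float(per_time.max())
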