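"""AUC feature extraction from plate time courses.

Converts two-channel fluorescence time courses into the scalar readouts the
landscape analysis consumes: the activity AUC (resorufin channel, a proxy for
aniline utilization) and the growth AUC (GFP channel, degrader growth), each
the trapezoidal time-integral of the blank-corrected trace in RFU.h.

The correction recipe is deliberately minimal and configurable: per channel
and time point, subtract the mean (or median) blank reading from every
non-blank well; no smoothing, no clipping of negative readings, integration
over the full common time window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import FUNCTION_COL, GROWTH_COL, REPLICATE_COL, LandscapeTable
from .panel import Membership, StrainPanel
from .plates import ACTIVITY, GROWTH, PlateTimeCourse


@dataclass
class WellFeatures:
    well_id: str
    composition: Membership
    activity_auc: float
    growth_auc: float | None = None


def auc_trapezoid(times_min: np.ndarray, rfu: np.ndarray) -> float:
    """Trapezoidal AUC of a fluorescence trace in RFU.h.

    Times are minutes, strictly increasing; negative readings are not
    clipped (blank correction can legitimately produce them).
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(rfu, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and rfu must have equal length")
    if len(t) < 2:
        raise ValueError("AUC needs at least 2 time points")
    if not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t / 60.0))


def blank_correct(plate: PlateTimeCourse, statistic: str = "mean") -> PlateTimeCourse:
    """Subtract the per-time-point blank signal from every non-blank well.

    ``statistic`` is ``mean`` (default) or ``median`` over the blank wells of
    the same channel.  Blank wells are removed from the output, which guards
    against accidental double correction: a second pass fails for lack of
    blanks.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown blank statistic {statistic!r}")
    df = plate.data
    blanks = df[df["blank"] == 1]
    samples = df[df["blank"] == 0].copy()
    for channel in sorted(samples["channel"].unique()):
        ch_blanks = blanks[blanks["channel"] == channel]
        if ch_blanks.empty:
            raise ValueError(f"no blank wells for channel {channel!r}; cannot blank-correct")
        agg = getattr(ch_blanks.groupby("time_min")["rfu"], statistic)()
        sel = samples["channel"] == channel
        correction = samples.loc[sel, "time_min"].map(agg)
        if correction.isna().any():
            raise ValueError(f"blank wells do not cover all time points for channel {channel!r}")
        samples.loc[sel, "rfu"] = samples.loc[sel, "rfu"] - correction
    return PlateTimeCourse(plate.panel, samples.reset_index(drop=True))


def extract_features(plate: PlateTimeCourse) -> list[WellFeatures]:
    """One :class:`WellFeatures` per non-blank well of a corrected plate.

    The activity channel is required per well; the growth channel is optional
    and yields ``growth_auc`` when present.
    """
    out = []
    for well in plate.wells(blank=False):
        composition = plate.composition_of(well)
        times, rfu = plate.trace(well, ACTIVITY)
        activity = auc_trapezoid(times, rfu)
        growth = None
        has_growth = not plate.data[
            (plate.data["well"] == well) & (plate.data["channel"] == GROWTH)
        ].empty
        if has_growth:
            gt, gr = plate.trace(well, GROWTH)
            growth = auc_trapezoid(gt, gr)
        out.append(WellFeatures(well, composition, activity, growth))
    return out


def assemble_landscape(features: list[WellFeatures], panel: StrainPanel) -> LandscapeTable:
    """Group per-well features into a landscape: wells sharing a composition
    become numbered replicates (in well-id order).  Compositions without
    wells are simply absent, so the landscape may be incomplete."""
    if not features:
        raise ValueError("no well features to assemble")
    rows = []
    counts: dict[Membership, int] = {}
    any_growth = any(f.growth_auc is not None for f in features)
    for f in sorted(features, key=lambda f: f.well_id):
        counts[f.composition] = counts.get(f.composition, 0) + 1
        row = dict(zip(panel.strain_ids, f.composition))
        row[REPLICATE_COL] = counts[f.composition]
        row[FUNCTION_COL] = f.activity_auc
        if any_growth:
            row[GROWTH_COL] = f.growth_auc if f.growth_auc is not None else np.nan
        rows.append(row)
    return LandscapeTable(panel, pd.DataFrame(rows))


def plate_to_landscape(plate: PlateTimeCourse, statistic: str = "mean") -> LandscapeTable:
    """Convenience pipeline: blank-correct, extract AUCs, assemble landscape."""
    corrected = blank_correct(plate, statistic=statistic)
    return assemble_landscape(extract_features(corrected), plate.panel)
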