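"""Two-channel plate-reader time courses (resorufin activity, GFP growth).

Long-format container: one row per (well, channel, time point) with columns
``well``, ``blank`` (0/1), one 0/1 column per panel strain, ``channel``
(``activity`` | ``growth``), ``time_min`` and ``rfu``.  Blank wells carry
all-zero strain columns and blank=1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import Membership, StrainPanel

ACTIVITY = "activity"
GROWTH = "growth"
CHANNELS = (ACTIVITY, GROWTH)


@dataclass
class PlateTimeCourse:
    panel: StrainPanel
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = ["well", "blank", *self.panel.strain_ids, "channel", "time_min", "rfu"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing plate column(s): {missing}")
        bad = ~df["channel"].isin(CHANNELS)
        if bad.any():
            raise ValueError(f"unknown channel value(s): {sorted(df.loc[bad, 'channel'].unique())}")
        for (well, channel), grp in df.groupby(["well", "channel"], sort=False):
            t = grp["time_min"].to_numpy(float)
            if len(t) < 1 or not (np.diff(t) > 0).all():
                raise ValueError(f"times not strictly increasing for well {well!r} channel {channel!r}")
        self.data = df

    @property
    def channels(self) -> list[str]:
        return sorted(self.data["channel"].unique())

    def wells(self, blank: bool | None = None) -> list[str]:
        df = self.data
        if blank is not None:
            df = df[df["blank"] == int(blank)]
        return sorted(df["well"].unique())

    def trace(self, well: str, channel: str) -> tuple[np.ndarray, np.ndarray]:
        grp = self.data[(self.data["well"] == well) & (self.data["channel"] == channel)]
        if grp.empty:
            raise KeyError(f"no trace for well {well!r} channel {channel!r}")
        return grp["time_min"].to_numpy(float), grp["rfu"].to_numpy(float)

    def composition_of(self, well: str) -> Membership:
        row = self.data[self.data["well"] == well].iloc[0]
        if row["blank"]:
            raise ValueError(f"well {well!r} is a blank")
        return tuple(int(row[s]) for s in self.panel.strain_ids)


def read_plate(path, panel: StrainPanel) -> PlateTimeCourse:
    return PlateTimeCourse(panel, pd.read_csv(path))


def write_plate(plate: PlateTimeCourse, path) -> None:
    cols = ["well", "blank", *plate.panel.strain_ids, "channel", "time_min", "rfu"]
    plate.data[cols].to_csv(path, index=False)
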