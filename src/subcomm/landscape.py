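"""The composition-function landscape table and its CSV round-trip.

A :class:`LandscapeTable` maps every observed subcommunity composition to its
replicate functional readouts (activity AUC, RFU.h) and, optionally, degrader
growth readouts (growth AUC).  The on-disk format is a comma-separated file
with one 0/1 column per panel strain, a ``replicate`` column, a
``function_auc`` column and an optional ``growth_auc`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import Membership, StrainPanel, membership_of_mask

logger = logging.getLogger(__name__)

FUNCTION_COL = "function_auc"
GROWTH_COL = "growth_auc"
REPLICATE_COL = "replicate"


@dataclass
class LandscapeTable:
    """Replicated composition -> function (and optional growth) measurements.

    ``records`` has one row per well/replicate with the panel's strain columns
    (0/1), ``replicate`` (int), ``function_auc`` (float) and optionally
    ``growth_auc`` (float).  (composition, replicate) pairs are unique and
    function values finite; the landscape is *complete* when all 2^p
    compositions are observed at least once.
    """

    panel: StrainPanel
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        missing = [c for c in (*self.panel.strain_ids, REPLICATE_COL, FUNCTION_COL) if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        strain_cols = list(self.panel.strain_ids)
        mem = df[strain_cols].to_numpy()
        bad = ~np.isin(mem, (0, 1))
        if bad.any():
            row = int(np.argwhere(bad.any(axis=1))[0][0])
            raise ValueError(
                f"non-binary membership value in row {row}: {df.loc[row, strain_cols].to_dict()}"
            )
        df[strain_cols] = mem.astype(np.int8)
        df[REPLICATE_COL] = df[REPLICATE_COL].astype(int)
        fv = df[FUNCTION_COL].astype(float)
        if not np.isfinite(fv).all():
            row = int(np.argwhere(~np.isfinite(fv.to_numpy()))[0][0])
            raise ValueError(f"non-finite function value in row {row}")
        df[FUNCTION_COL] = fv
        if GROWTH_COL in df.columns:
            df[GROWTH_COL] = df[GROWTH_COL].astype(float)
        dup = df.duplicated(subset=strain_cols + [REPLICATE_COL])
        if dup.any():
            row = int(np.argwhere(dup.to_numpy())[0][0])
            raise ValueError(
                f"duplicate (composition, replicate) pair at row {row}: "
                f"replicate {df.loc[row, REPLICATE_COL]} of "
                f"{df.loc[row, strain_cols].to_dict()}"
            )
        self.records = df

    # -- basic queries -----------------------------------------------------

    @property
    def p(self) -> int:
        return self.panel.p

    @property
    def has_growth(self) -> bool:
        return GROWTH_COL in self.records.columns and self.records[GROWTH_COL].notna().any()

    def masks(self) -> np.ndarray:
        """Bitmask per record row."""
        mem = self.records[list(self.panel.strain_ids)].to_numpy()
        return mem @ (1 << np.arange(self.p))

    def compositions(self) -> list[Membership]:
        return sorted({membership_of_mask(int(m), self.p) for m in self.masks()})

    def missing_compositions(self) -> list[Membership]:
        seen = set(int(m) for m in self.masks())
        return [membership_of_mask(m, self.p) for m in range(2 ** self.p) if m not in seen]

    @property
    def is_complete(self) -> bool:
        return len(set(int(m) for m in self.masks())) == 2 ** self.p

    # -- aggregation -------------------------------------------------------

    def mean_by_mask(self, column: str = FUNCTION_COL) -> dict[int, float]:
        """Replicate-mean of a value column keyed by composition bitmask."""
        df = self.records.assign(_mask=self.masks())
        return df.groupby("_mask")[column].mean().to_dict()

    def mean_function(self) -> dict[Membership, float]:
        return {
            membership_of_mask(m, self.p): v for m, v in self.mean_by_mask(FUNCTION_COL).items()
        }

    def mean_growth(self) -> dict[Membership, float] | None:
        if not self.has_growth:
            return None
        return {
            membership_of_mask(m, self.p): v for m, v in self.mean_by_mask(GROWTH_COL).items()
        }


def replicate_means(
    landscape: LandscapeTable,
) -> dict[Membership, tuple[float, float | None]]:
    """Per-composition arithmetic means of function (and growth, if present).

    Compositions observed with a single replicate pass through unchanged; the
    result is invariant to replicate ordering.
    """
    if len(landscape.records) == 0:
        raise ValueError("empty landscape")
    mf = landscape.mean_function()
    mg = landscape.mean_growth()
    return {c: (mf[c], mg[c] if mg is not None else None) for c in mf}


def read_landscape(path, panel: StrainPanel) -> LandscapeTable:
    """Read a landscape CSV (see module docstring for the column contract).

    Raises a ``ValueError`` naming the offending row for non-binary
    membership values or duplicated (composition, replicate) pairs, and for
    missing required columns.  A missing ``growth_auc`` column only disables
    growth analyses (logged, not an error).
    """
    df = pd.read_csv(path)
    if GROWTH_COL not in df.columns:
        logger.warning("no %s column in %s: growth analyses disabled", GROWTH_COL, path)
    return LandscapeTable(panel, df)


def write_landscape(landscape: LandscapeTable, path) -> None:
    cols = list(landscape.panel.strain_ids) + [REPLICATE_COL, FUNCTION_COL]
    if GROWTH_COL in landscape.records.columns:
        cols.append(GROWTH_COL)
    landscape.records[cols].to_csv(path, index=False)


def landscape_from_values(
    panel: StrainPanel,
    values: Mapping[Membership, float] | Mapping[Membership, list[float]],
    growth: Mapping[Membership, float] | None = None,
) -> LandscapeTable:
    """Build a LandscapeTable from a composition -> value(s) mapping (test/fixture aid)."""
    rows = []
    for mem, val in values.items():
        reps = val if isinstance(val, (list, tuple, np.ndarray)) else [val]
        for r, v in enumerate(reps, start=1):
            row = dict(zip(panel.strain_ids, mem))
            row[REPLICATE_COL] = r
            row[FUNCTION_COL] = float(v)
            if growth is not None:
                row[GROWTH_COL] = float(growth[mem])
            rows.append(row)
    return LandscapeTable(panel, pd.DataFrame(rows))
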