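"""Empirical quantities of the composition-function landscape.

Given a replicated landscape this module computes, on replicate means per
composition:

* **functional effects** -- for a focal strain i and background S (i absent),
  ``Delta_i(S) = v(S + i) - v(S)``: one hypercube edge per observed
  background (128 per strain on a complete p=8 landscape);
* **Shapley values** -- each strain's average marginal functional
  contribution over all orderings in which the full community can be
  assembled, computed exactly by subset weighting
  ``phi_i = sum_S |S|! (p-1-|S|)!/p! * Delta_i(S)`` (an explicit
  all-orderings oracle is provided for cross-checking; p=8 means 8! = 40320
  assembly pathways);
* **pairwise functional interactions** -- ``I_ij = mean(Delta_i | j present)
  - mean(Delta_i | j absent)`` with a two-sided Welch t-test over
  backgrounds (64 vs 64 per pair at p=8), positive = synergistic, negative =
  subadditive; no multiplicity correction by default, Benjamini-Hochberg
  optional;
* **growth-function effect correlations** -- per-strain Pearson r between a
  strain's growth effect and its functional effect across backgrounds;
* **global-epistasis fits** -- per-strain OLS of Delta_i(S) against the
  background function level v(S).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import LandscapeTable
from .panel import Membership, membership_of_mask

logger = logging.getLogger(__name__)


@dataclass
class EffectEdge:
    """One landscape edge: effect of adding ``focal`` to ``background``."""

    focal: str
    background: Membership
    delta_function: float
    delta_growth: float | None = None
    background_function: float | None = None


@dataclass
class ShapleyVector:
    strain_ids: tuple[str, ...]
    phi: np.ndarray
    n_backgrounds: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.phi, index=list(self.strain_ids), name="phi")

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"strain": self.strain_ids, "phi": self.phi})
        df["rank"] = df["phi"].rank(ascending=False).astype(int)
        return df


def _require_complete(landscape: LandscapeTable, what: str) -> None:
    if not landscape.is_complete:
        missing = landscape.missing_compositions()
        shown = ", ".join(str(m) for m in missing[:8])
        more = "" if len(missing) <= 8 else f" (+{len(missing) - 8} more)"
        raise ValueError(f"{what} requires a complete landscape; missing compositions: {shown}{more}")


# ---------------------------------------------------------------------------
# functional effects


def functional_effects(landscape: LandscapeTable, focal: str) -> list[EffectEdge]:
    """All observable effect edges of a focal strain, on replicate means.

    One edge per background with both endpoint compositions observed; raises
    if no edge is computable for the strain.
    """
    p = landscape.p
    i = landscape.panel.index_of(focal)
    bit = 1 << i
    means = landscape.mean_by_mask()
    gmeans = landscape.mean_by_mask("growth_auc") if landscape.has_growth else None
    edges = []
    for s_mask, v_s in means.items():
        if s_mask & bit:
            continue
        up = s_mask | bit
        if up not in means:
            continue
        dg = None
        if gmeans is not None and s_mask in gmeans and up in gmeans:
            dg = gmeans[up] - gmeans[s_mask]
        edges.append(
            EffectEdge(
                focal=focal,
                background=membership_of_mask(s_mask, p),
                delta_function=means[up] - v_s,
                delta_growth=dg,
                background_function=v_s,
            )
        )
    if not edges:
        raise ValueError(f"no computable effect edges for focal strain {focal!r}")
    edges.sort(key=lambda e: e.background)
    return edges


def effects_table(landscape: LandscapeTable) -> pd.DataFrame:
    """Long table of every strain's effect edges (one row per edge)."""
    rows = []
    for strain in landscape.panel.strain_ids:
        for e in functional_effects(landscape, strain):
            rows.append(
                {
                    "focal": e.focal,
                    "background": "".join(map(str, e.background)),
                    "background_function": e.background_function,
                    "delta_function": e.delta_function,
                    "delta_growth": e.delta_growth,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shapley values


def shapley_exact(landscape: LandscapeTable) -> ShapleyVector:
    """Exact Shapley values by subset weighting.

    ``phi_i = sum_{S subset of N\\{i}} |S|! (p-1-|S|)! / p! * Delta_i(S)``,
    mathematically identical to averaging marginal contributions over all p!
    assembly orderings but evaluated in O(p * 2^p).  Requires a complete
    landscape (exactness is impossible otherwise).
    """
    _require_complete(landscape, "shapley_exact")
    p = landscape.p
    means = landscape.mean_by_mask()
    w = np.array(
        [factorial(s) * factorial(p - 1 - s) / factorial(p) for s in range(p)]
    )
    phi = np.zeros(p)
    popcounts = np.array([bin(m).count("1") for m in range(2 ** p)])
    for i in range(p):
        bit = 1 << i
        for s_mask in range(2 ** p):
            if s_mask & bit:
                continue
            phi[i] += w[popcounts[s_mask]] * (means[s_mask | bit] - means[s_mask])
    return ShapleyVector(landscape.panel.strain_ids, phi, n_backgrounds=2 ** (p - 1))


def shapley_by_orderings(landscape: LandscapeTable, max_p: int = 9) -> ShapleyVector:
    """Oracle Shapley: explicit average over all p! assembly orderings.

    Traverses every ordering of the p nondegraders (p=8: 40320 pathways) and
    averages each strain's marginal contribution.  Guarded at ``max_p``
    strains; use :func:`shapley_exact` beyond that.
    """
    _require_complete(landscape, "shapley_by_orderings")
    p = landscape.p
    if p > max_p:
        raise ValueError(f"p={p} exceeds the factorial guard ({max_p}); use shapley_exact")
    means = landscape.mean_by_mask()
    phi = np.zeros(p)
    count = 0
    for order in permutations(range(p)):
        mask = 0
        for i in order:
            new = mask | (1 << i)
            phi[i] += means[new] - means[mask]
            mask = new
        count += 1
    phi /= count
    return ShapleyVector(landscape.panel.strain_ids, phi, n_backgrounds=2 ** (p - 1))


# ---------------------------------------------------------------------------
# pairwise functional interactions


def interaction_matrix(
    landscape: LandscapeTable,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Pairwise functional interactions with Welch t-tests.

    For every ordered pair (focal i, partner j): strength
    ``I_ij = mean(Delta_i(S) | j in S) - mean(Delta_i(S) | j not in S)``,
    two-sided Welch t statistic and p value treating backgrounds as
    independent observations.  On a complete landscape the strength is
    symmetric (I_ij = I_ji), both reducing to the average second difference.
    ``correction='bh'`` applies Benjamini-Hochberg across pairs (off by
    default: significance is reported on raw p values).

    Returns a long DataFrame with columns focal, partner, strength, t, p,
    n_with, n_without, significant, flagged (flagged = fewer than 2 effects
    in either group, p undefined).
    """
    if correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    panel = landscape.panel
    p = panel.p
    rows = []
    for i, focal in enumerate(panel.strain_ids):
        edges = functional_effects(landscape, focal)
        deltas = np.array([e.delta_function for e in edges])
        has_j = np.array([[e.background[j] == 1 for e in edges] for j in range(p)])
        for j, partner in enumerate(panel.strain_ids):
            if j == i:
                continue
            a = deltas[has_j[j]]
            b = deltas[~has_j[j]]
            flagged = len(a) < 2 or len(b) < 2
            strength = (a.mean() if len(a) else np.nan) - (b.mean() if len(b) else np.nan)
            if flagged:
                t_stat, p_val = np.nan, np.nan
            else:
                t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "focal": focal,
                    "partner": partner,
                    "strength": strength,
                    "t": t_stat,
                    "p": p_val,
                    "n_with": len(a),
                    "n_without": len(b),
                    "flagged": flagged,
                }
            )
    df = pd.DataFrame(rows)
    pvals = df["p"]
    if correction == "bh":
        ok = pvals.notna()
        adj = pvals.copy()
        if ok.any():
            from statsmodels.stats.multitest import multipletests

            adj.loc[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        df["p_adjusted"] = adj
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = pvals < alpha
    return df


def strength_matrix(interactions: pd.DataFrame, strain_ids: tuple[str, ...]) -> pd.DataFrame:
    """Pivot the long interaction table into a p x p strength matrix."""
    mat = interactions.pivot(index="focal", columns="partner", values="strength")
    mat = mat.reindex(index=list(strain_ids), columns=list(strain_ids))
    np.fill_diagonal(mat.values, 0.0)
    return mat


def significant_interaction_counts(interactions: pd.DataFrame) -> tuple[int, int]:
    """(negative, positive) significant counts over unordered pairs (i<j)."""
    df = interactions[interactions["focal"] < interactions["partner"]]
    sig = df[df["significant"].fillna(False)]
    return int((sig["strength"] < 0).sum()), int((sig["strength"] > 0).sum())


# ---------------------------------------------------------------------------
# growth-function correlation and global epistasis


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def growth_function_correlation(landscape: LandscapeTable) -> pd.DataFrame:
    """Per-strain Pearson correlation between growth and function effects.

    Across a strain's effect edges, correlates Delta_growth with
    Delta_function (two-sided p value, star-coded).  Edges lacking either
    delta are dropped; strains with fewer than 3 usable edges or zero
    variance in either delta are flagged (r undefined).
    """
    if not landscape.has_growth:
        raise ValueError("landscape has no growth values")
    rows = []
    for strain in landscape.panel.strain_ids:
        edges = [e for e in functional_effects(landscape, strain) if e.delta_growth is not None]
        dg = np.array([e.delta_growth for e in edges])
        df_ = np.array([e.delta_function for e in edges])
        flagged = len(edges) < 3 or np.ptp(dg) == 0 or np.ptp(df_) == 0
        if flagged:
            r, p_val = np.nan, np.nan
        else:
            r, p_val = stats.pearsonr(dg, df_)
        rows.append(
            {
                "strain": strain,
                "r": r,
                "p": p_val,
                "n": len(edges),
                "stars": significance_stars(p_val),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def global_epistasis_fit(landscape: LandscapeTable) -> pd.DataFrame:
    """Per-strain OLS of functional effect against background function level.

    The global-epistasis pattern: effects tend to be positive on low-function
    backgrounds and negative on high-function ones, i.e. a negative slope.
    Strains with fewer than 3 edges or a degenerate predictor are flagged.
    """
    rows = []
    for strain in landscape.panel.strain_ids:
        edges = functional_effects(landscape, strain)
        x = np.array([e.background_function for e in edges])
        y = np.array([e.delta_function for e in edges])
        flagged = len(edges) < 3 or np.ptp(x) == 0
        if flagged:
            slope = intercept = r = p_val = np.nan
        else:
            res = stats.linregress(x, y)
            slope, intercept, r, p_val = res.slope, res.intercept, res.rvalue, res.pvalue
        rows.append(
            {
                "strain": strain,
                "slope": slope,
                "intercept": intercept,
                "r": r,
                "p": p_val,
                "n": len(edges),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
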