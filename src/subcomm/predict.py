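"""Bottom-up prediction of community function from subcommunity data.

Random-forest regressors are trained on the presence/absence vectors of
subcommunities at fixed richness levels (response: replicate-mean activity
AUC) and evaluated on the pooled 5-to-(p+1)-member communities (p=8: n=163
test compositions) by Pearson correlation between predicted and observed
function.  Training sets may be randomly subsampled (e.g. to 50% or 25%) to
probe performance under limited data, and the whole procedure is repeated
over many seeds (default 100), reporting mean +/- SD and the
median-performance repeat (the 51st of 100 after ascending sort).

Leakage control: when a test composition also occurs in the training set,
the model is refit with exactly that one composition removed and the refit
model is used for that composition only.

Hyperparameters default to classic random-forest regression settings:
500 trees, mtry = max(1, floor(p/3)) features per split, unlimited depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .landscape import LandscapeTable
from .panel import Membership, enumerate_pool, richness

logger = logging.getLogger(__name__)


@dataclass
class TrainingRegime:
    """One training condition: which richness levels, what subsample fraction."""

    richness_levels: tuple[int, ...]
    fraction: float = 1.0
    n_trees: int = 500
    mtry: int | None = None  # default max(1, floor(p/3))

    def __post_init__(self) -> None:
        self.richness_levels = tuple(sorted(int(r) for r in self.richness_levels))
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")

    @property
    def label(self) -> str:
        levels = ",".join(map(str, self.richness_levels))
        return f"richness{{{levels}}}@{self.fraction:g}"


@dataclass
class RegimeResult:
    regime: TrainingRegime
    rs: np.ndarray  # per-repeat Pearson r on the test pool
    n_train: int  # unique training compositions (before subsampling)
    seeds: np.ndarray

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.rs))

    @property
    def sd_r(self) -> float:
        return float(np.std(self.rs, ddof=1)) if len(self.rs) > 1 else 0.0

    @property
    def median_repeat(self) -> int:
        """Index of the median-performance repeat: the (n//2 + 1)-th of n in
        ascending order (51st of 100), ties broken by repeat index."""
        order = np.argsort(self.rs, kind="stable")
        return int(order[len(self.rs) // 2])

    @property
    def median_seed(self) -> int:
        return int(self.seeds[self.median_repeat])


def build_design_matrix(
    landscape: LandscapeTable, richness_levels
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix over unique observed compositions at given richness.

    One row per unique composition (presence/absence of the p nondegraders,
    columns in panel order), response = replicate-mean function.  The counts
    quoted for the study design (n=28 three-member, n=163 test pool, ...)
    are therefore row counts.
    """
    levels = set(int(r) for r in richness_levels)
    means = landscape.mean_function()
    comps = sorted(c for c in means if richness(c) in levels)
    if not comps:
        raise ValueError(f"no observed compositions at richness levels {sorted(levels)}")
    X = pd.DataFrame(comps, columns=list(landscape.panel.strain_ids))
    y = pd.Series([means[c] for c in comps], name="function_auc")
    return X, y


def fit_regressor(
    X, y, n_trees: int = 500, mtry: int | None = None, seed: int = 0
) -> RandomForestRegressor:
    """Fit the random-forest regressor; deterministic given the seed.

    A constant response is allowed (the forest predicts the constant; a
    debug message is logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    if np.ptp(y) == 0:
        logger.debug("constant response: model will predict %g everywhere", y[0])
    p = X.shape[1]
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry if mtry is not None else max(1, p // 3),
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def evaluate_regime(
    landscape: LandscapeTable,
    regime: TrainingRegime,
    seed: int = 0,
    test_richness: tuple[int, ...] | None = None,
    leakage_removal: bool = True,
) -> dict:
    """One repeat: subsample, fit, leakage-safe predict, Pearson r.

    Subsampling draws ``floor(fraction * n_train)`` compositions without
    replacement.  Returns a dict with r, n_train_used, n_refits and the
    per-composition predictions.
    """
    panel = landscape.panel
    p = panel.p
    if test_richness is None:
        test_richness = tuple(range(5, p + 2))
    X, y = build_design_matrix(landscape, regime.richness_levels)
    rng = np.random.default_rng(seed)
    n = len(X)
    n_used = max(2, int(np.floor(regime.fraction * n))) if regime.fraction < 1 else n
    idx = np.sort(rng.choice(n, size=n_used, replace=False)) if n_used < n else np.arange(n)
    Xs, ys = X.iloc[idx].reset_index(drop=True), y.iloc[idx].reset_index(drop=True)

    model_seed = int(rng.integers(0, 2**31 - 1))
    model = fit_regressor(Xs, ys, regime.n_trees, regime.mtry, seed=model_seed)

    means = landscape.mean_function()
    test_comps = [c for c in enumerate_pool(panel, test_richness) if c in means]
    if not test_comps:
        raise ValueError(f"no observed test compositions at richness {test_richness}")
    X_test = np.array(test_comps, dtype=float)
    pred = model.predict(X_test)

    train_set = {tuple(int(v) for v in row) for row in Xs.to_numpy()}
    n_refits = 0
    if leakage_removal:
        for t, comp in enumerate(test_comps):
            if comp in train_set:
                keep = [k for k in range(len(Xs)) if tuple(int(v) for v in Xs.iloc[k]) != comp]
                if not keep:
                    raise ValueError("cannot refit: training set reduces to nothing")
                refit = fit_regressor(
                    Xs.iloc[keep], ys.iloc[keep], regime.n_trees, regime.mtry, seed=model_seed
                )
                pred[t] = refit.predict(X_test[t : t + 1])[0]
                n_refits += 1

    obs = np.array([means[c] for c in test_comps])
    r = float(stats.pearsonr(pred, obs)[0]) if np.ptp(pred) > 0 else np.nan
    return {
        "r": r,
        "n_train": n,
        "n_train_used": n_used,
        "n_refits": n_refits,
        "test_compositions": test_comps,
        "predicted": pred,
        "observed": obs,
        "model_seed": model_seed,
    }


def run_regime_suite(
    landscape: LandscapeTable,
    regimes: list[TrainingRegime],
    n_repeats: int = 100,
    base_seed: int = 0,
    test_richness: tuple[int, ...] | None = None,
) -> list[RegimeResult]:
    """Repeat every regime ``n_repeats`` times with seeds base_seed+k."""
    results = []
    for regime in regimes:
        seeds = np.arange(base_seed, base_seed + n_repeats)
        rs = np.empty(n_repeats)
        n_train = 0
        for k, s in enumerate(seeds):
            out = evaluate_regime(landscape, regime, seed=int(s), test_richness=test_richness)
            rs[k] = out["r"]
            n_train = out["n_train"]
        results.append(RegimeResult(regime, rs, n_train, seeds))
        logger.info(
            "%s: mean r=%.3f sd=%.3f (n_train=%d, %d repeats)",
            regime.label, results[-1].mean_r, results[-1].sd_r, n_train, n_repeats,
        )
    return results


def regime_results_table(results: list[RegimeResult]) -> pd.DataFrame:
    rows = [
        {
            "regime": res.regime.label,
            "richness_levels": ",".join(map(str, res.regime.richness_levels)),
            "fraction": res.regime.fraction,
            "n_train": res.n_train,
            "n_repeats": len(res.rs),
            "mean_r": res.mean_r,
            "sd_r": res.sd_r,
            "median_repeat": res.median_repeat,
            "median_repeat_seed": res.median_seed,
            "median_r": float(res.rs[res.median_repeat]),
        }
        for res in results
    ]
    return pd.DataFrame(rows)


def regime_repeats_table(results: list[RegimeResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for k, (s, r) in enumerate(zip(res.seeds, res.rs)):
            rows.append({"regime": res.regime.label, "repeat": k, "seed": int(s), "r": r})
    return pd.DataFrame(rows)
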