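"""Model-agnostic interpretation: permutation importance and Friedman's H.

Both metrics are computed from a fitted model (anything exposing
``predict(X) -> array``) against a reference design matrix, by default the
model's own training rows.

Friedman's H for a feature pair (j, k) compares the model's joint
partial-dependence surface to the sum of the marginal partial dependences:

    H^2 = sum_rows [PD_jk(x_j, x_k) - PD_j(x_j) - PD_k(x_k)]^2
          / sum_rows [PD_jk(x_j, x_k)]^2

with all PDs mean-centered under the empirical feature-value frequencies of
the reference rows; H = sqrt(H^2) in [0, 1] up to estimation noise, 0 for a
purely additive model.  A denominator below tolerance (near-constant model)
maps to H = 0 rather than 0/0.

Permutation importance of feature j is the increase in mean-squared
prediction error after randomly shuffling column j, averaged over k
permutations (or over all distinct permutations when exhaustive).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .effects import ShapleyVector

DENOM_TOL = 1e-12


class FunctionModel:
    """Wrap an exact function of the feature row as a predict-able model.

    Used for analytic worked examples and oracles, e.g.
    ``FunctionModel(lambda x: x[0] * x[1])``.
    """

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.fn(row) for row in X], dtype=float)


def partial_dependence(model, X_ref, features) -> dict[tuple[int, ...], float]:
    """Centered partial dependence of 1 or 2 binary features.

    PD(g) = mean over reference rows of the model prediction with the
    feature(s) forced to grid value g, for g on {0,1}^d; the returned values
    are centered by the PD mean weighted by the empirical frequencies of the
    observed feature values in X_ref.
    """
    X_ref = np.asarray(X_ref, dtype=float)
    if X_ref.size == 0:
        raise ValueError("X_ref must be non-empty")
    features = tuple(int(f) for f in features)
    grid = list(product((0.0, 1.0), repeat=len(features)))
    stacked = []
    for g in grid:
        Xg = X_ref.copy()
        for f, val in zip(features, g):
            Xg[:, f] = val
        stacked.append(Xg)
    preds = model.predict(np.vstack(stacked)).reshape(len(grid), len(X_ref))
    pd_raw = {g: float(preds[t].mean()) for t, g in enumerate(grid)}
    observed = [tuple(row[list(features)]) for row in X_ref]
    weights = {g: observed.count(g) / len(observed) for g in grid}
    center = sum(weights[g] * pd_raw[g] for g in grid)
    return {g: pd_raw[g] - center for g in grid}


def friedman_h_pair(
    model, X_ref, j: int, k: int, tol: float = DENOM_TOL, _marginals=None
) -> tuple[float, float]:
    """Friedman's H for feature pair (j, k) against the reference rows.

    Returns (H, denominator); H = 0 when the denominator (the joint-PD
    second moment over the reference rows) is below ``tol``.  Raises for a
    feature constant in X_ref.  ``_marginals`` lets :func:`h_matrix` reuse
    precomputed one-feature partial dependences.
    """
    X_ref = np.asarray(X_ref, dtype=float)
    for f in (j, k):
        if np.ptp(X_ref[:, f]) == 0:
            raise ValueError(f"feature {f} is constant in the reference rows; H undefined")
    marg = _marginals or {}
    pd_j = marg.get(j) or partial_dependence(model, X_ref, (j,))
    pd_k = marg.get(k) or partial_dependence(model, X_ref, (k,))
    pd_jk = partial_dependence(model, X_ref, (j, k))
    num = den = 0.0
    for row in X_ref:
        xj, xk = float(row[j]), float(row[k])
        joint = pd_jk[(xj, xk)]
        num += (joint - pd_j[(xj,)] - pd_k[(xk,)]) ** 2
        den += joint**2
    if den < tol:
        return 0.0, den
    return float(np.sqrt(num / den)), den


def h_matrix(model, X_ref, feature_names=None, tol: float = DENOM_TOL) -> pd.DataFrame:
    """Long-format H table over all feature pairs (j < k).

    Columns: j, k, H, denominator, flagged (degenerate denominator or a
    constant feature).
    """
    X_ref = np.asarray(X_ref, dtype=float)
    p = X_ref.shape[1]
    names = list(feature_names) if feature_names is not None else list(range(p))
    marginals = {
        j: partial_dependence(model, X_ref, (j,))
        for j in range(p)
        if np.ptp(X_ref[:, j]) > 0
    }
    rows = []
    for j in range(p):
        for k in range(j + 1, p):
            try:
                h, den = friedman_h_pair(model, X_ref, j, k, tol=tol, _marginals=marginals)
                flagged = den < tol
            except ValueError:
                h, den, flagged = np.nan, np.nan, True
            rows.append({"j": names[j], "k": names[k], "H": h, "denominator": den, "flagged": flagged})
    return pd.DataFrame(rows)


@dataclass
class ImportanceVector:
    feature_names: list
    importance: np.ndarray  # increase in MSE, function-units^2
    sd: np.ndarray  # MC SD over permutations
    k_perms: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"strain": self.feature_names, "importance": self.importance, "sd": self.sd}
        )


def permutation_importance(
    model,
    X_ref,
    y_ref,
    k_perms: int = 50,
    seed: int = 0,
    exhaustive: bool = False,
    feature_names=None,
) -> ImportanceVector:
    """Permutation importance: mean MSE increase after shuffling a column.

    With ``exhaustive=True`` all n! distinct permutations of the column are
    enumerated (guarded at n <= 8 rows), giving the exact expectation the
    Monte-Carlo default converges to.
    """
    X_ref = np.asarray(X_ref, dtype=float)
    y_ref = np.asarray(y_ref, dtype=float)
    n, p = X_ref.shape
    if n < 2:
        raise ValueError("need at least 2 reference rows")
    names = list(feature_names) if feature_names is not None else list(range(p))
    base_mse = float(np.mean((model.predict(X_ref) - y_ref) ** 2))
    rng = np.random.default_rng(seed)
    imp = np.zeros(p)
    sd = np.zeros(p)
    if exhaustive and n > 8:
        raise ValueError("exhaustive enumeration guarded at 8 rows")
    for jcol in range(p):
        perms = (
            [np.array(q) for q in iter_permutations(range(n))]
            if exhaustive
            else [rng.permutation(n) for _ in range(k_perms)]
        )
        increases = np.empty(len(perms))
        for t, q in enumerate(perms):
            Xp = X_ref.copy()
            Xp[:, jcol] = X_ref[q, jcol]
            mse = float(np.mean((model.predict(Xp) - y_ref) ** 2))
            increases[t] = mse - base_mse
        imp[jcol] = increases.mean()
        sd[jcol] = increases.std(ddof=1) if len(increases) > 1 else 0.0
    return ImportanceVector(names, imp, sd, len(perms))


def compare_to_empirical(
    importances: ImportanceVector,
    h_table: pd.DataFrame,
    shapley: ShapleyVector,
    interactions: pd.DataFrame,
    signed: bool = False,
) -> pd.DataFrame:
    """Correlate model-derived metrics with the empirical landscape metrics.

    Rows: (a) permutation importance vs |Shapley| (Pearson and Spearman over
    strains), (b) H vs interaction strength over the unordered strain pairs
    (absolute strength by default, since H is unsigned; ``signed=True``
    compares against the signed strength instead).  Degenerate-variance
    comparisons are flagged with r = NaN.
    """
    rows = []

    def corr_row(metric, x, y, n):
        x, y = np.asarray(x, float), np.asarray(y, float)
        flagged = n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0
        if flagged:
            r = p_val = rho = rho_p = np.nan
        else:
            r, p_val = stats.pearsonr(x, y)
            rho, rho_p = stats.spearmanr(x, y)
        return {
            "metric": metric, "r": r, "p": p_val,
            "spearman_rho": rho, "spearman_p": rho_p, "n": n, "flagged": flagged,
        }

    imp = np.array([importances.importance[importances.feature_names.index(s)] for s in shapley.strain_ids])
    rows.append(corr_row("importance_vs_abs_shapley", imp, np.abs(shapley.phi), len(imp)))

    pairs = interactions[interactions["focal"] < interactions["partner"]]
    key = lambda a, b: (a, b) if a < b else (b, a)
    strength = {key(r_["focal"], r_["partner"]): r_["strength"] for _, r_ in pairs.iterrows()}
    hv, sv = [], []
    for _, row in h_table.iterrows():
        kk = key(row["j"], row["k"])
        if kk in strength and np.isfinite(row["H"]):
            hv.append(row["H"])
            sv.append(strength[kk] if signed else abs(strength[kk]))
    label = "h_vs_signed_interaction" if signed else "h_vs_abs_interaction"
    rows.append(corr_row(label, hv, sv, len(hv)))
    return pd.DataFrame(rows)
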