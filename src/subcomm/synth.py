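"""Synthetic composition-function landscapes with known ground truth.

The generator emulates the statistical structure of a replicated full
factorial subcommunity assay: additive per-strain functional effects
perturbed by signed pairwise interactions and homoscedastic Gaussian
replicate noise.  For a composition S the noiseless function value is

    v*(S) = beta0 + sum_{i in S} beta_i + sum_{i<j in S} gamma_ij

and every replicate adds Normal(0, sigma_noise).  Because the generator is
pairwise, the downstream estimators have closed-form targets: the exact
Shapley value of v* is beta_i + 1/2 * sum_j gamma_ij and the pairwise
functional-interaction statistic recovers gamma_ij exactly on noiseless
data.  Third-order terms are available through ``third_order`` but are off
by default, keeping ground truth identifiable by pairwise statistics.

A coupled degrader-growth landscape and two-channel logistic plate time
courses (with blank wells and drift) are also generated so the AUC feature
extraction can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .landscape import FUNCTION_COL, GROWTH_COL, REPLICATE_COL, LandscapeTable
from .panel import Membership, StrainPanel, default_panel, membership_of_mask
from .plates import ACTIVITY, GROWTH, PlateTimeCourse


@dataclass
class LandscapeParams:
    """Ground-truth parameters of a synthetic landscape.

    beta0 is the degrader-alone baseline, ``beta`` the length-p main effects,
    ``gamma`` a symmetric zero-diagonal p x p pairwise interaction matrix,
    ``sigma_noise`` the replicate noise SD (same units as the function,
    RFU.h) and ``n_reps`` the replicates per composition.
    """

    panel: StrainPanel
    beta0: float
    beta: np.ndarray
    gamma: np.ndarray
    sigma_noise: float = 0.0
    n_reps: int = 1
    seed: int = 0
    third_order: dict[tuple[int, int, int], float] | None = None

    def __post_init__(self) -> None:
        p = self.panel.p
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != (p,):
            raise ValueError(f"beta must have shape ({p},)")
        if self.gamma.shape != (p, p):
            raise ValueError(f"gamma must have shape ({p}, {p})")
        if not np.allclose(self.gamma, self.gamma.T):
            raise ValueError("gamma must be symmetric")
        if np.diag(self.gamma).any():
            raise ValueError("gamma must have zero diagonal")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class GrowthCouplingParams:
    """Couples strain effects on degrader growth to their functional effects.

    ``delta`` are additive per-strain effects on degrader growth AUC;
    ``kappa`` maps a strain's growth effect into its functional main effect,
    so the effective function main effect becomes
    ``kappa_i * delta_i + beta_i`` where the accompanying
    :class:`LandscapeParams` ``beta`` plays the role of a growth-independent
    residual.  Strains with kappa>0 and zero residual act purely through
    degrader growth promotion (perfect dG-dF coupling); strains with kappa=0
    act through other mechanisms.

    ``gamma_growth`` (optional, symmetric, zero diagonal) gives the growth
    landscape pairwise structure, making a strain's growth effect vary
    across backgrounds; the function channel inherits each growth
    interaction scaled by the mean kappa of the pair.  With uniform kappa=c,
    zero residuals and no function-specific interactions, every strain's
    functional effect is exactly c times its growth effect across all
    backgrounds (Pearson r = 1).  Without it the noiseless growth effect of
    a strain is the same in every background and the per-strain dG-dF
    correlation is degenerate (flagged downstream).
    """

    delta: np.ndarray
    kappa: np.ndarray
    sigma_growth: float = 0.0
    g0: float = 0.0
    gamma_growth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.sigma_growth < 0:
            raise ValueError("sigma_growth must be >= 0")
        if self.gamma_growth is not None:
            self.gamma_growth = np.asarray(self.gamma_growth, dtype=float)
            if not np.allclose(self.gamma_growth, self.gamma_growth.T) or np.diag(
                self.gamma_growth
            ).any():
                raise ValueError("gamma_growth must be symmetric with zero diagonal")


@dataclass
class EpistasisParams:
    """Global-epistasis slope: a strain's effect declines linearly with the
    functional level of its background community (slope ``lambda_ge``)."""

    lambda_ge: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_ge):
            raise ValueError("lambda_ge must be finite")


# ---------------------------------------------------------------------------
# landscape generation


def _membership_matrix(p: int) -> np.ndarray:
    """(2^p, p) matrix of all membership vectors, row index = bitmask."""
    masks = np.arange(2 ** p)[:, None]
    return ((masks >> np.arange(p)) & 1).astype(np.int8)


def noiseless_values(params: LandscapeParams) -> np.ndarray:
    """v*(S) for every composition, indexed by bitmask."""
    M = _membership_matrix(params.panel.p).astype(float)
    v = params.beta0 + M @ params.beta + 0.5 * np.einsum("si,ij,sj->s", M, params.gamma, M)
    if params.third_order:
        for (i, j, k), w in params.third_order.items():
            v += w * M[:, i] * M[:, j] * M[:, k]
    return v


def generate_landscape(params: LandscapeParams) -> LandscapeTable:
    """Complete 2^p landscape with n_reps noisy replicates per composition.

    Fully reproducible from ``params.seed``: the same parameters always
    produce an identical table.
    """
    rng = np.random.default_rng(params.seed)
    p, n = params.panel.p, params.n_reps
    v = noiseless_values(params)
    M = _membership_matrix(p)
    rows = np.repeat(np.arange(2 ** p), n)
    noise = rng.normal(0.0, params.sigma_noise, size=len(rows)) if params.sigma_noise > 0 else 0.0
    df = pd.DataFrame(M[rows], columns=list(params.panel.strain_ids))
    df[REPLICATE_COL] = np.tile(np.arange(1, n + 1), 2 ** p)
    df[FUNCTION_COL] = v[rows] + noise
    return LandscapeTable(params.panel, df)


def closed_form_shapley(params: LandscapeParams) -> np.ndarray:
    """Exact Shapley value of the noiseless generator: beta_i + 1/2 sum_j gamma_ij."""
    if params.third_order:
        phi = params.beta + 0.5 * params.gamma.sum(axis=1)
        for (i, j, k), w in params.third_order.items():
            for idx in (i, j, k):
                phi[idx] += w / 3.0
        return phi
    return params.beta + 0.5 * params.gamma.sum(axis=1)


def closed_form_interactions(params: LandscapeParams) -> np.ndarray:
    """The pairwise functional-interaction statistic of the noiseless
    generator equals gamma exactly (averaging over backgrounds cancels all
    other pairwise terms)."""
    return params.gamma.copy()


def _coupled_function_params(
    params: LandscapeParams, coupling: GrowthCouplingParams
) -> LandscapeParams:
    """Function-channel parameters implied by growth coupling: effective main
    effects kappa*delta + residual beta, plus growth interactions inherited
    scaled by the pair-mean kappa."""
    p = params.panel.p
    if coupling.delta.shape != (p,) or coupling.kappa.shape != (p,):
        raise ValueError(f"delta and kappa must have shape ({p},)")
    gamma_eff = params.gamma
    if coupling.gamma_growth is not None:
        kbar = 0.5 * (coupling.kappa[:, None] + coupling.kappa[None, :])
        gamma_eff = params.gamma + kbar * coupling.gamma_growth
    return LandscapeParams(
        panel=params.panel,
        beta0=params.beta0,
        beta=coupling.kappa * coupling.delta + params.beta,
        gamma=gamma_eff,
        sigma_noise=params.sigma_noise,
        n_reps=params.n_reps,
        seed=params.seed,
        third_order=params.third_order,
    )


def _growth_values_for(coupling: GrowthCouplingParams, M: np.ndarray) -> np.ndarray:
    """Noiseless growth AUC per membership row."""
    g = coupling.g0 + M @ coupling.delta
    if coupling.gamma_growth is not None:
        g = g + 0.5 * np.einsum("si,ij,sj->s", M, coupling.gamma_growth, M)
    return g


def generate_growth_coupled_landscape(
    params: LandscapeParams, coupling: GrowthCouplingParams
) -> LandscapeTable:
    """Landscape with a coupled degrader-growth channel.

    Growth of composition S is ``g0 + sum_{i in S} delta_i`` plus
    Normal(0, sigma_growth) per replicate; the function landscape uses
    effective main effects ``kappa_i * delta_i + beta_i`` (see
    :class:`GrowthCouplingParams`).
    """
    eff = _coupled_function_params(params, coupling)
    table = generate_landscape(eff)
    rng = np.random.default_rng(params.seed + 1)
    M = table.records[list(params.panel.strain_ids)].to_numpy(float)
    g = _growth_values_for(coupling, M)
    if coupling.sigma_growth > 0:
        g = g + rng.normal(0.0, coupling.sigma_growth, size=len(g))
    df = table.records.copy()
    df[GROWTH_COL] = g
    return LandscapeTable(params.panel, df)


def generate_epistatic_landscape(
    panel: StrainPanel,
    epi: EpistasisParams,
    baseline: float = 100.0,
    scale: float = 100.0,
    sigma_noise: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> LandscapeTable:
    """Landscape exhibiting exact global epistasis.

    Uses ``v*(S) = baseline + scale * (1 + lambda_ge)^|S|``, so every strain's
    functional effect satisfies
    ``Delta_i(S) = lambda_ge * v*(S) - lambda_ge * baseline`` exactly:
    a linear dependence on background function with slope ``lambda_ge`` and
    intercept ``-lambda_ge * baseline``, identical for all strains.
    """
    rng = np.random.default_rng(seed)
    p = panel.p
    M = _membership_matrix(p)
    v = baseline + scale * (1.0 + epi.lambda_ge) ** M.sum(axis=1)
    rows = np.repeat(np.arange(2 ** p), n_reps)
    noise = rng.normal(0.0, sigma_noise, size=len(rows)) if sigma_noise > 0 else 0.0
    df = pd.DataFrame(M[rows], columns=list(panel.strain_ids))
    df[REPLICATE_COL] = np.tile(np.arange(1, n_reps + 1), 2 ** p)
    df[FUNCTION_COL] = v[rows] + noise
    return LandscapeTable(panel, df)


# ---------------------------------------------------------------------------
# study-scale preset


def study_preset(
    seed: int = 0,
    p: int = 8,
    n_reps: int = 4,
    sigma_noise: float = 1.5e3,
    beta_sd: float = 6.0e3,
    gamma_sd: float = 6.0e3,
    gamma_density: float = 0.46,
    beta0: float = 2.0e4,
) -> LandscapeParams:
    """Study-scale preset: p=8 strains, 4 replicates per composition.

    Effect magnitudes are on a plate-reader AUC scale (RFU.h over 72 h):
    strong main effects (SD 6e3) relative to replicate noise (SD 1.5e3),
    with a signed pairwise interaction structure strong enough that strain
    effects can flip sign across backgrounds (each pair active with
    probability 0.46 -- roughly the empirically observed fraction of
    significant pairs in a community of this kind -- with SD equal to the
    main-effect SD).  Parameters are drawn reproducibly from ``seed``; the
    replicate-noise draw uses the same seed downstream.
    """
    rng = np.random.default_rng(seed)
    beta = rng.normal(0.0, beta_sd, size=p)
    gamma = np.zeros((p, p))
    for i, j in combinations(range(p), 2):
        if rng.random() < gamma_density:
            gamma[i, j] = gamma[j, i] = rng.normal(0.0, gamma_sd)
    return LandscapeParams(
        panel=default_panel(p),
        beta0=beta0,
        beta=beta,
        gamma=gamma,
        sigma_noise=sigma_noise,
        n_reps=n_reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plate time courses


@dataclass
class PlateKinetics:
    """Logistic fluorescence rise: midpoint and steepness in hours, sampled
    every ``interval_min`` minutes over ``duration_h`` hours (the study's
    72 h at 10 min -> 433 points per well)."""

    t_mid_h: float = 24.0
    tau_h: float = 4.0
    duration_h: float = 72.0
    interval_min: float = 10.0


def generate_plate_timecourse(
    params: LandscapeParams,
    kinetics: PlateKinetics | None = None,
    blank_drift: tuple[float, float] = (50.0, 0.5),
    n_blank_wells: int = 4,
    noise_sd: float = 0.0,
    seed: int | None = None,
    coupling: GrowthCouplingParams | None = None,
) -> PlateTimeCourse:
    """Two-channel plate with known underlying landscape.

    Each non-blank well reads ``blank_drift(t) + A_S * logistic(t)`` where the
    amplitude A_S is chosen so the blank-corrected trapezoidal AUC equals the
    target noiseless landscape value v*(S) (activity channel) or g*(S)
    (growth channel, when ``coupling`` is given).  Blank wells carry the
    drift alone plus optional Gaussian read noise.  ``blank_drift`` is
    (offset RFU, slope RFU/min).
    """
    kin = kinetics or PlateKinetics()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    p = params.panel.p
    t_min = np.arange(0.0, kin.duration_h * 60.0 + kin.interval_min / 2, kin.interval_min)
    t_h = t_min / 60.0
    logistic = 1.0 / (1.0 + np.exp(-(t_h - kin.t_mid_h) / kin.tau_h))
    unit_auc = np.trapezoid(logistic, t_h)  # RFU.h per unit amplitude
    drift = blank_drift[0] + blank_drift[1] * t_min

    if coupling is not None:
        v_act = noiseless_values(_coupled_function_params(params, coupling))
        M = _membership_matrix(p).astype(float)
        v_gro = _growth_values_for(coupling, M)
    else:
        v_act = noiseless_values(params)
        v_gro = None

    channels = [(ACTIVITY, v_act)] + ([(GROWTH, v_gro)] if v_gro is not None else [])
    frames = []

    def well_frame(well_id, blank, membership, channel, rfu):
        d = {s: m for s, m in zip(params.panel.strain_ids, membership)}
        return pd.DataFrame(
            {"well": well_id, "blank": int(blank), **d, "channel": channel,
             "time_min": t_min, "rfu": rfu}
        )

    w = 0
    for mask in range(2 ** p):
        membership = membership_of_mask(mask, p)
        for rep in range(params.n_reps):
            w += 1
            well_id = f"W{w:04d}"
            for channel, v in channels:
                amp = v[mask] / unit_auc
                rfu = drift + amp * logistic
                if noise_sd > 0:
                    rfu = rfu + rng.normal(0.0, noise_sd, size=len(rfu))
                frames.append(well_frame(well_id, False, membership, channel, rfu))
    zero = (0,) * p
    for b in range(n_blank_wells):
        well_id = f"B{b + 1:02d}"
        for channel, _ in channels:
            rfu = drift.copy()
            if noise_sd > 0:
                rfu = rfu + rng.normal(0.0, noise_sd, size=len(rfu))
            frames.append(well_frame(well_id, True, zero, channel, rfu))

    return PlateTimeCourse(params.panel, pd.concat(frames, ignore_index=True))
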