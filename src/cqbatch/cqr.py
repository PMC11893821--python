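"""Stage 2b: composite quantile regression and the reference-batch transport.

For each OTU the nonzero stage-1 counts are modelled by quantile regression
over a grid tau_s = s/(k+1), s = 1..k (default k = 19, i.e. the 5th..95th
percentiles).  The composite mode minimises the summed check loss with ONE
shared slope vector (covariates alpha, batch delta) and per-tau intercepts;
``per_tau`` mode fits each level independently.  Combined with the logistic
nonzero probability q_ij this yields a zero-inflated quantile function

    Qc(tau) = 0                         if tau <  1 - q
    Qc(tau) = Qpos((tau - (1-q)) / q)   if tau >= 1 - q

per (sample, batch) context.  A sample's observed value is converted to its
quantile level under its own batch's context and re-read under the reference
batch's context, which transports every batch onto the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .data import CountTable, StudyDesign
from .zeros import ZeroFit, batch_columns, predict_q_matrix

logger = logging.getLogger(__name__)

DEFAULT_K = 19


def default_tau_grid(k: int = DEFAULT_K) -> np.ndarray:
    """Quantile levels s/(k+1), s = 1..k."""
    return np.arange(1, k + 1) / (k + 1)


def check_loss(u, tau: float):
    """Check loss rho_tau(u) = u * (tau - 1{u < 0}); non-negative everywhere."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie strictly inside (0, 1)")
    u = np.asarray(u, float)
    out = u * (tau - (u < 0))
    return float(out) if out.ndim == 0 else out


@dataclass
class CQRFit:
    """Per-OTU stage-2 quantile-regression parameters.

    In composite mode ``alpha``/``delta`` are 1-D (shared across tau); in
    per_tau mode they are (k, p) matrices.  ``intercepts`` holds b(tau_s).
    ``y_min`` floors every predicted quantile at the smallest observed
    positive value so the positive branch stays positive.
    """

    otu_id: str
    tau_grid: np.ndarray
    mode: str                     # "composite" | "per_tau" | "empirical"
    alpha: np.ndarray
    delta: np.ndarray
    intercepts: np.ndarray
    covariate_names: tuple
    batch_names: tuple            # non-reference batch labels (delta order)
    y_min: float
    objective: float = float("nan")
    fallback: bool = False
    empirical_grid: dict = field(default_factory=dict)  # batch -> quantiles


def _solve_lp(y, M, taus):
    """Minimise sum_s sum_i rho_{tau_s}(y_i - b_s - m_i'w) by linear programming.

    Variables are per-tau intercepts b, shared slopes w, and residual splits
    u, v >= 0.  Returns (b, w) or None on solver failure.
    """
    n, p = M.shape
    K = taus.size
    nk = n * K
    A = sp.hstack(
        [
            sp.kron(sp.eye(K), np.ones((n, 1))),
            sp.kron(np.ones((K, 1)), sp.csr_matrix(M)) if p else sp.csr_matrix((nk, 0)),
            sp.eye(nk),
            -sp.eye(nk),
        ],
        format="csc",
    )
    c = np.concatenate([np.zeros(K + p), np.repeat(taus, n), np.repeat(1 - taus, n)])
    bounds = [(None, None)] * (K + p) + [(0, None)] * (2 * nk)
    for method in ("highs-ipm", "highs"):
        res = linprog(c, A_eq=A, b_eq=np.tile(y, K), bounds=bounds, method=method)
        if res.status == 0:
            z = res.x
            return z[:K], z[K : K + p]
    return None


def _objective(y, M, taus, intercepts, W):
    """Summed check loss of Eq-style predictions; W is (k, p) slope matrix."""
    total = 0.0
    for s, tau in enumerate(taus):
        resid = y - intercepts[s] - (M @ W[s] if M.shape[1] else 0.0)
        total += float(np.sum(check_loss(resid, tau)))
    return total


def fit_cqr_otu(
    y_star: np.ndarray,
    X: pd.DataFrame,
    B: pd.DataFrame,
    tau_grid: np.ndarray | None = None,
    mode: str = "composite",
    otu_id: str = "",
) -> CQRFit:
    """Fit quantile regression on one OTU's nonzero adjusted counts.

    Too few observations (fewer than #covariates + #batch columns + k) or a
    solver failure trigger a per-batch empirical-quantile fallback, flagged.
    Intercepts are monotone-rearranged (sorted) so grid predictions cannot
    cross in composite mode; per-sample rearrangement happens at prediction.
    """
    if mode not in ("composite", "per_tau"):
        raise ValueError(f"unknown mode {mode!r}")
    taus = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    if not (np.all(np.diff(taus) > 0) and 0 < taus[0] and taus[-1] < 1):
        raise ValueError("tau grid must be strictly increasing inside (0, 1)")
    y = np.asarray(y_star, float)
    if np.any(y <= 0):
        raise ValueError("fit_cqr_otu expects the nonzero subset")
    M = pd.concat([X, B], axis=1).to_numpy(dtype=float)
    p = M.shape[1]
    K = taus.size
    names = (tuple(X.columns), tuple(B.columns))
    y_min = float(y.min())

    if y.size < p + K:
        return _empirical_fallback(y, B, taus, otu_id, names, y_min,
                                   note="too few nonzero observations")

    if mode == "composite":
        sol = _solve_lp(y, M, taus)
        if sol is None:
            return _empirical_fallback(y, B, taus, otu_id, names, y_min,
                                       note="LP solver failure")
        b, w = sol
        b = np.sort(b)  # monotone rearrangement of the per-tau intercepts
        alpha, delta = w[: X.shape[1]], w[X.shape[1] :]
        W = np.tile(w, (K, 1))
    else:
        bs, Ws = [], []
        for tau in taus:
            sol = _solve_lp(y, M, np.array([tau]))
            if sol is None:
                return _empirical_fallback(y, B, taus, otu_id, names, y_min,
                                           note=f"LP solver failure at tau={tau}")
            bi, wi = sol
            bs.append(bi[0])
            Ws.append(wi)
        b = np.array(bs)
        W = np.array(Ws)
        alpha, delta = W[:, : X.shape[1]], W[:, X.shape[1] :]
    obj = _objective(y, M, taus, b, W)
    return CQRFit(otu_id, taus, mode, np.asarray(alpha), np.asarray(delta), b,
                  names[0], names[1], y_min, objective=obj)


def _empirical_fallback(y, B, taus, otu_id, names, y_min, note="") -> CQRFit:
    """Per-batch empirical quantiles when regression is ill-posed."""
    logger.info("OTU %s: empirical-quantile fallback (%s)", otu_id, note)
    grid = {"__all__": np.quantile(y, taus)}
    ref_rows = B.to_numpy().sum(axis=1) == 0
    if ref_rows.sum() >= 3:
        grid[""] = np.quantile(y[ref_rows], taus)
    for g in B.columns:
        rows = B[g].to_numpy() > 0
        if rows.sum() >= 3:
            grid[g] = np.quantile(y[rows], taus)
    return CQRFit(otu_id, taus, "empirical", np.zeros(0), np.zeros(0),
                  grid["__all__"], names[0], names[1], y_min, fallback=True,
                  empirical_grid=grid)


def _grid_matrix(fit: CQRFit, X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(n, k) predicted grid values, monotone-rearranged rows, floored at y_min."""
    n = X.shape[0]
    if fit.mode == "empirical":
        G = np.empty((n, fit.tau_grid.size))
        batch_of_row = np.full(n, "", dtype=object)
        for j, g in enumerate(fit.batch_names):
            batch_of_row[B[:, j] > 0] = g
        for i in range(n):
            key = batch_of_row[i]
            G[i] = fit.empirical_grid.get(key, fit.empirical_grid["__all__"])
    elif fit.mode == "composite":
        shift = X @ fit.alpha + B @ fit.delta
        G = fit.intercepts[None, :] + shift[:, None]
    else:  # per_tau
        G = fit.intercepts[None, :] + X @ fit.alpha.T + B @ fit.delta.T
    G = np.sort(G, axis=1)
    return np.maximum(G, fit.y_min)


def predict_quantile(fit: CQRFit, X_row, B_row, tau: float) -> float:
    """Positive-branch quantile at level tau for one context.

    Piecewise-linear between grid levels, constant beyond the grid ends,
    floored at the OTU's smallest observed positive value.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    X_row = np.asarray(X_row, float)[None, :]
    B_row = np.asarray(B_row, float)[None, :]
    if X_row.shape[1] != len(fit.covariate_names) or B_row.shape[1] != len(fit.batch_names):
        raise ValueError("dimension mismatch with fitted coefficients")
    g = _grid_matrix(fit, X_row, B_row)[0]
    return float(np.interp(tau, fit.tau_grid, g))


@dataclass
class ZIQuantileFunction:
    """Zero-inflated composite quantile function for one (sample, context)."""

    q: float                      # nonzero probability
    tau_grid: np.ndarray
    grid_values: np.ndarray       # positive-branch values at tau_grid, sorted

    def positive_qf(self, tau_prime: float) -> float:
        return float(np.interp(tau_prime, self.tau_grid, self.grid_values))


def zi_quantile(qf: ZIQuantileFunction, tau: float) -> float:
    """Two-branch rule: 0 below the zero mass, rescaled positive branch above."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if tau < 1 - qf.q:
        return 0.0
    return qf.positive_qf((tau - (1 - qf.q)) / qf.q)


def _level_in_grid(tau, g, y):
    """Midpoint of the preimage interval of y under the grid qf (scalar)."""
    y = min(max(y, g[0]), g[-1])
    j_left = int(np.searchsorted(g, y, side="left"))
    j_right = int(np.searchsorted(g, y, side="right"))
    if j_left < j_right:  # y equals one or more knot values
        lo = 0.0 if j_left == 0 else tau[j_left]
        hi = 1.0 if j_right == len(g) else tau[j_right - 1]
        return (lo + hi) / 2.0
    frac = (y - g[j_left - 1]) / (g[j_left] - g[j_left - 1])
    return tau[j_left - 1] + frac * (tau[j_left] - tau[j_left - 1])


def zi_quantile_level(qf: ZIQuantileFunction, y: float) -> float:
    """Quantile level of an observed value under the zero-inflated qf.

    Zeros sit at the midpoint of the zero mass, (1 - q)/2.  Positive values
    invert the positive branch (midpoint of flat stretches); values below the
    branch minimum clamp to the first grid level.
    """
    if y < 0:
        raise ValueError("counts are non-negative")
    if y == 0:
        return (1 - qf.q) / 2.0
    tau_p = _level_in_grid(qf.tau_grid, qf.grid_values, y)
    return (1 - qf.q) + qf.q * tau_p


def _levels_of_values(tau, G, y):
    """Vectorised :func:`_level_in_grid` across rows of G."""
    n, K = G.shape
    y = np.clip(y, G[:, 0], G[:, -1])
    yc = y[:, None]
    j_left = (G < yc).sum(axis=1)
    j_right = (G <= yc).sum(axis=1)
    out = np.empty(n)
    exact = j_left < j_right
    if exact.any():
        lo = np.where(j_left[exact] == 0, 0.0, tau[np.minimum(j_left[exact], K - 1)])
        hi = np.where(j_right[exact] == K, 1.0, tau[np.clip(j_right[exact] - 1, 0, K - 1)])
        out[exact] = (lo + hi) / 2.0
    interp = ~exact
    if interp.any():
        j = j_left[interp]
        g_hi = G[interp, j]
        g_lo = G[interp, j - 1]
        frac = (y[interp] - g_lo) / (g_hi - g_lo)
        out[interp] = tau[j - 1] + frac * (tau[j] - tau[j - 1])
    return out


def _values_at_levels(tau, G, tau_p):
    """Row-wise linear interpolation of G at levels tau_p (constant beyond ends)."""
    tau_p = np.clip(tau_p, tau[0], tau[-1])
    j = np.clip(np.searchsorted(tau, tau_p, side="left"), 1, tau.size - 1)
    t_lo, t_hi = tau[j - 1], tau[j]
    frac = (tau_p - t_lo) / (t_hi - t_lo)
    rows = np.arange(G.shape[0])
    return G[rows, j - 1] + frac * (G[rows, j] - G[rows, j - 1])


def fit_cqr_model(
    stage1: CountTable,
    design: StudyDesign,
    reference: str,
    tau_grid: np.ndarray | None = None,
    mode: str = "composite",
) -> dict[str, CQRFit]:
    """Fit the stage-2 quantile model for every OTU of the stage-1 table."""
    B = batch_columns(design, reference)
    X = design.covariates
    fits = {}
    for otu in stage1.otu_ids:
        col = stage1.counts[otu].to_numpy()
        nz = col > 0
        fits[otu] = fit_cqr_otu(col[nz], X.loc[nz], B.loc[nz],
                                tau_grid=tau_grid, mode=mode, otu_id=otu)
    return fits


def correct_nonsystematic(
    stage1: CountTable,
    design: StudyDesign,
    zero_fits: dict[str, ZeroFit],
    cqr_fits: dict[str, CQRFit],
    reference: str,
    uncorrectable: set | None = None,
    stochastic_zeros: bool = False,
    seed: int = 0,
) -> CountTable:
    """Transport every sample's values onto the reference batch's distributions.

    Per (sample, OTU): the observed stage-1 value's quantile level under the
    sample's own-batch zero-inflated quantile function is re-read under the
    reference-batch context (same covariates, reference batch indicators);
    the result is rounded half-to-even to a non-negative integer.  Reference
    samples and upstream-uncorrectable OTUs pass through unchanged.

    Zeros sit at the midpoint of the zero mass by default (deterministic);
    with ``stochastic_zeros`` their level is drawn uniformly on (0, 1 - q)
    using ``seed``, which preserves distributional spread at the cost of
    run-to-run variability.
    """
    rng = np.random.default_rng(seed)
    uncorrectable = uncorrectable or set()
    counts = stage1.counts
    B_own = batch_columns(design, reference)
    B_ref = pd.DataFrame(0.0, index=B_own.index, columns=B_own.columns)
    X = design.covariates
    Xn = X.to_numpy()
    Bn_own = B_own.to_numpy()
    Bn_ref = B_ref.to_numpy()
    in_ref = (design.batch == reference).to_numpy()
    out = counts.to_numpy().astype(float).copy()

    for j, otu in enumerate(stage1.otu_ids):
        if otu in uncorrectable:
            continue
        zfit, cfit = zero_fits[otu], cqr_fits[otu]
        q_own = predict_q_matrix(zfit, X, B_own)
        q_ref = predict_q_matrix(zfit, X, B_ref)
        G_own = _grid_matrix(cfit, Xn, Bn_own)
        G_ref = _grid_matrix(cfit, Xn, Bn_ref)
        y = counts[otu].to_numpy().astype(float)
        tau = cfit.tau_grid

        zero_levels = ((1 - q_own) * rng.random(y.size) if stochastic_zeros
                       else (1 - q_own) / 2.0)
        tau_obs = np.where(
            y == 0,
            zero_levels,
            (1 - q_own) + q_own * _levels_of_values(tau, G_own, y),
        )
        zero_branch = tau_obs < (1 - q_ref)
        tau_ref = np.clip((tau_obs - (1 - q_ref)) / q_ref, 0.0, 1.0)
        vals = _values_at_levels(tau, G_ref, tau_ref)
        corrected = np.where(zero_branch, 0.0, np.round(vals))
        corrected = np.maximum(corrected, 0.0)
        out[:, j] = np.where(in_ref, y, corrected)

    return CountTable(
        pd.DataFrame(out.astype(np.int64), index=counts.index, columns=counts.columns),
        library_sizes=stage1.library_sizes.copy(),
    )
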