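"""Stage 1: removal of systematic (mean-shift) batch effects.

Each OTU's nonzero counts are modelled as negative binomial with
log mu_ijg = sigma_j + X_i' beta_j + gamma_jg + log N_i, where N_i is the
total library size and gamma_jg is a per-batch fixed effect under a
sample-size-weighted sum-to-zero constraint.  The batch-free mean is
log mu_ij* = log mu_ijg - gamma_jg; per-batch dispersions theta_jg are
averaged into theta_j*.  Every nonzero count is then quantile-mapped from
its fitted zero-truncated NB(mu_ijg, theta_jg) onto the batch-free
zero-truncated NB(mu_ij*, theta_j*).  Zeros are untouched by this stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountTable, StudyDesign

logger = logging.getLogger(__name__)

THETA_FLOOR = 1e-4
THETA_CAP = 1e4
_PMAX = 1.0 - 1e-10


@dataclass
class NBFit:
    """Per-OTU stage-1 parameters.

    ``gamma`` maps batch label -> batch effect on the log-mean scale; the
    weighted sum over batches (weights = nonzero observations per batch) is
    zero.  ``mu``/``mu_star`` are fitted and batch-free means indexed by the
    nonzero samples the model was fitted on.
    """

    otu_id: str
    sigma: float
    beta: dict[str, float]
    gamma: dict[str, float]
    theta: dict[str, float]
    theta_star: float
    mu: pd.Series
    mu_star: pd.Series
    converged: bool
    uncorrectable: bool = False
    note: str = ""


def nb_variance(mu: float, theta: float) -> float:
    """NB2 variance mu + theta * mu**2 (theta = 0 recovers Poisson)."""
    if np.any(np.asarray(mu) < 0) or np.any(np.asarray(theta) < 0):
        raise ValueError("mu and theta must be non-negative")
    return mu + theta * mu**2


def _nb_rp(mu, theta):
    """scipy parameterisation (r, p) of NB with mean mu, dispersion theta."""
    theta = np.maximum(theta, THETA_FLOOR)
    r = 1.0 / theta
    return r, r / (r + mu)


def _map_counts(y, mu_src, theta_src, mu_tgt, theta_tgt, rng=None):
    """Vectorised quantile map of positive counts between zero-truncated NBs.

    The source quantile level is the midpoint-CDF level
    p = (F(y-1) + F(y)) / 2 under the >0-truncated source distribution; the
    mapped value is the smallest positive integer whose truncated target CDF
    reaches p.  With ``rng`` the level is drawn uniformly on
    [F(y-1), F(y)] instead (randomised quantile residual), trading the
    deterministic default for distributional fidelity.
    """
    y = np.asarray(y, dtype=np.int64)
    r_s, p_s = _nb_rp(np.asarray(mu_src, float), np.asarray(theta_src, float))
    r_t, p_t = _nb_rp(np.asarray(mu_tgt, float), np.asarray(theta_tgt, float))
    f0_s = stats.nbinom.cdf(0, r_s, p_s)
    denom = 1.0 - f0_s
    with np.errstate(divide="ignore", invalid="ignore"):
        ft_y = (stats.nbinom.cdf(y, r_s, p_s) - f0_s) / denom
        ft_ym1 = np.where(y > 1, (stats.nbinom.cdf(y - 1, r_s, p_s) - f0_s) / denom, 0.0)
    if rng is None:
        p_mid = (ft_y + ft_ym1) / 2.0
    else:
        p_mid = ft_ym1 + rng.random(y.shape) * (ft_y - ft_ym1)
    p_mid = np.clip(p_mid, 1e-12, _PMAX)
    f0_t = stats.nbinom.cdf(0, r_t, p_t)
    u = np.clip(f0_t + p_mid * (1.0 - f0_t), 0.0, _PMAX)
    out = stats.nbinom.ppf(u, r_t, p_t)
    out = np.maximum(out, 1).astype(np.int64)
    # degenerate source (essentially no positive mass): leave untouched
    degenerate = denom < 1e-12
    return np.where(degenerate, y, out)


def quantile_map_count(y: int, source: tuple[float, float], target: tuple[float, float]) -> int:
    """Map one positive count from source (mu, theta) to target (mu, theta)."""
    if y < 1:
        raise ValueError("stage 1 maps only positive counts")
    if min(source[0], target[0]) <= 0:
        raise ValueError("means must be positive")
    return int(_map_counts(np.array([y]), source[0], source[1], target[0], target[1])[0])


def _constrained_batch_design(batch_codes: np.ndarray, n_g: np.ndarray) -> np.ndarray:
    """Columns encoding gamma_1..gamma_{k-1} with sum_g n_g gamma_g = 0.

    The last batch's effect is implied: gamma_k = -sum_{g<k} n_g gamma_g / n_k.
    """
    k = len(n_g)
    cols = np.zeros((batch_codes.size, k - 1))
    for g in range(k - 1):
        cols[:, g] = (batch_codes == g).astype(float)
        cols[batch_codes == k - 1, g] = -n_g[g] / n_g[k - 1]
    return cols


def fit_nb_otu(
    y: np.ndarray,
    X: np.ndarray,
    batch: np.ndarray,
    offset: np.ndarray,
    otu_id: str = "",
    sample_ids=None,
    covariate_names=None,
    batch_levels=None,
) -> NBFit:
    """Fit the stage-1 NB regression on one OTU's nonzero counts.

    ``y`` must already be the nonzero subset; ``offset`` is log N_i.  The
    global dispersion is estimated jointly by maximum likelihood, then
    per-batch dispersions are re-estimated by moment matching of squared
    residuals against the fitted means (floored at 1e-4, capped at 1e4).
    Non-convergence falls back to a Poisson fit with theta = 1e-4.
    """
    from statsmodels.discrete.discrete_model import NegativeBinomial
    import statsmodels.api as sm

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    offset = np.asarray(offset, float)
    if batch_levels is None:
        batch_levels = sorted(set(batch))
    codes = np.array([batch_levels.index(b) for b in batch])
    k = len(batch_levels)
    n_g = np.array([(codes == g).sum() for g in range(k)], dtype=float)
    if sample_ids is None:
        sample_ids = np.arange(y.size)
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(X.shape[1])]

    parts = [np.ones((y.size, 1)), X]
    if k > 1:
        if (n_g == 0).any():
            return _uncorrectable(otu_id, sample_ids, y, "batch with no nonzero counts")
        parts.append(_constrained_batch_design(codes, n_g))
    Z = np.column_stack(parts)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        return _uncorrectable(otu_id, sample_ids, y, "singular design on nonzero subset")

    converged, params, theta_global = False, None, THETA_FLOOR
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = NegativeBinomial(y, Z, offset=offset).fit(
                disp=0, maxiter=200, method="bfgs", warn_convergence=False
            )
        alpha = float(res.params[-1])
        if res.mle_retvals.get("converged", False) and np.isfinite(res.params).all() and alpha > 0:
            converged = True
            params = np.asarray(res.params[:-1], float)
            theta_global = float(np.clip(alpha, THETA_FLOOR, THETA_CAP))
    except Exception:  # noqa: BLE001 - any optimiser failure routes to Poisson
        pass
    if not converged:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, Z, family=sm.families.Poisson(), offset=offset).fit()
            params = np.asarray(res.params, float)
            theta_global = THETA_FLOOR
        except Exception:
            return _uncorrectable(otu_id, sample_ids, y, "fit failed")

    eta = Z @ params + offset
    mu = np.exp(np.clip(eta, -700, 700))
    sigma = float(params[0])
    beta = dict(zip(covariate_names, params[1 : 1 + X.shape[1]]))
    if k > 1:
        g_free = params[1 + X.shape[1] :]
        gamma_vec = np.append(g_free, -(n_g[:-1] @ g_free) / n_g[-1])
    else:
        gamma_vec = np.zeros(1)
    gamma = dict(zip(batch_levels, gamma_vec))

    theta = {
        lev: _batch_theta(y[codes == g], mu[codes == g], theta_global)
        for g, lev in enumerate(batch_levels)
    }
    theta_star = float(np.mean(list(theta.values())))
    mu_star = mu * np.exp(-gamma_vec[codes])
    return NBFit(
        otu_id=otu_id,
        sigma=sigma,
        beta=beta,
        gamma=gamma,
        theta=theta,
        theta_star=theta_star,
        mu=pd.Series(mu, index=sample_ids),
        mu_star=pd.Series(mu_star, index=sample_ids),
        converged=converged,
    )


def _batch_theta(y, mu, theta_init: float) -> float:
    """Per-batch dispersion: 1-D MLE of the zero-truncated NB with fixed means.

    Fitting happens on the nonzero subset, so the plain moment estimator is
    biased low (truncation removes the low tail); maximizing the >0-truncated
    likelihood in theta alone removes that bias at negligible cost.
    """
    from scipy.optimize import minimize_scalar

    if y.size < 3:
        return theta_init

    def nll(log_theta):
        r = 1.0 / np.exp(log_theta)
        p = r / (r + mu)
        with np.errstate(divide="ignore"):
            ll = stats.nbinom.logpmf(y, r, p) - np.log1p(-stats.nbinom.pmf(0, r, p))
        return -float(np.sum(ll))

    res = minimize_scalar(nll, bounds=(np.log(THETA_FLOOR), np.log(THETA_CAP)),
                          method="bounded", options={"xatol": 1e-4})
    if not np.isfinite(res.fun):
        return theta_init
    return float(np.clip(np.exp(res.x), THETA_FLOOR, THETA_CAP))


def _uncorrectable(otu_id, sample_ids, y, note) -> NBFit:
    logger.warning("OTU %s uncorrectable in stage 1: %s", otu_id, note)
    empty = pd.Series(np.asarray(y, float), index=sample_ids)
    return NBFit(otu_id, 0.0, {}, {}, {}, THETA_FLOOR, empty, empty,
                 converged=False, uncorrectable=True, note=note)


def correct_systematic(
    table: CountTable,
    design: StudyDesign,
    stochastic_map: bool = False,
    seed: int = 0,
) -> tuple[CountTable, dict[str, NBFit]]:
    """Apply the stage-1 NB adjustment to every OTU of an aligned, filtered table.

    Returns the adjusted table (same shape, zeros preserved positionally) and
    the per-OTU fits.  OTUs whose fit is uncorrectable pass through unchanged.
    ``stochastic_map`` jitters each count's CDF level uniformly within its
    probability interval (seeded) instead of using the midpoint.
    """
    rng = np.random.default_rng(seed) if stochastic_map else None
    counts = table.counts
    X = design.covariates.to_numpy()
    batch = design.batch.to_numpy()
    offset = np.log(table.library_sizes.to_numpy().astype(float))
    levels = design.batch_levels
    out = counts.to_numpy().copy()
    fits: dict[str, NBFit] = {}
    for j, otu in enumerate(table.otu_ids):
        col = counts[otu].to_numpy()
        nz = col > 0
        fit = fit_nb_otu(
            col[nz], X[nz], batch[nz], offset[nz],
            otu_id=otu,
            sample_ids=counts.index[nz],
            covariate_names=list(design.covariates.columns),
            batch_levels=levels,
        )
        fits[otu] = fit
        if fit.uncorrectable:
            continue
        codes = np.array([levels.index(b) for b in batch[nz]])
        theta_src = np.array([fit.theta[levels[c]] for c in codes])
        out[nz, j] = _map_counts(
            col[nz], fit.mu.to_numpy(), theta_src,
            fit.mu_star.to_numpy(), fit.theta_star, rng=rng,
        )
    stage1 = CountTable(
        pd.DataFrame(out, index=counts.index, columns=counts.columns),
        library_sizes=table.library_sizes.copy(),
    )
    return stage1, fits
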