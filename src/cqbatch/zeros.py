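"""Stage 2a: per-OTU logistic model of the probability of a nonzero count.

q_ij = expit(X_i' zeta + B_i' psi) feeds the zero-inflated quantile function:
the bottom 1 - q_ij of probability mass is the zero mass.  Batch enters as a
fixed-effect indicator vector reference-coded against the selected reference
batch, so the reference context is simply B = 0.  A small ridge penalty
guards against quasi-separation in sparse OTUs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .data import CountTable, StudyDesign

logger = logging.getLogger(__name__)

Q_CLAMP = 1e-6
RIDGE_LAMBDA = 1e-4


def batch_columns(design: StudyDesign, reference: str) -> pd.DataFrame:
    """Reference-coded batch indicators: one column per non-reference batch."""
    levels = [g for g in design.batch_levels if g != reference]
    return pd.DataFrame(
        {g: (design.batch == g).astype(float) for g in levels},
        index=design.batch.index,
    )


@dataclass
class ZeroFit:
    """Per-OTU logistic fit: intercept+covariate coefficients and batch shifts."""

    otu_id: str
    zeta: pd.Series          # "(intercept)" + covariate names
    psi: pd.Series           # one entry per non-reference batch
    q: pd.Series             # fitted nonzero probabilities, clamped
    separation_flag: bool = False
    dropped_columns: tuple = ()


def _clamp(p):
    return np.clip(p, Q_CLAMP, 1.0 - Q_CLAMP)


def fit_zero_otu(
    y_star: np.ndarray,
    X: pd.DataFrame,
    B: pd.DataFrame,
    otu_id: str = "",
) -> ZeroFit:
    """Ridge-penalised logistic regression of 1{y* > 0} on [X | B].

    All-nonzero and all-zero OTUs get constant q at the clamp boundary with
    ``separation_flag`` set.  Exactly collinear batch columns are dropped
    (coefficient 0) before fitting.
    """
    ind = (np.asarray(y_star) > 0).astype(int)
    idx = X.index
    cov_names = ["(intercept)", *X.columns]
    if ind.all() or not ind.any():
        const = 1.0 - Q_CLAMP if ind.all() else Q_CLAMP
        return ZeroFit(
            otu_id,
            zeta=pd.Series(0.0, index=cov_names),
            psi=pd.Series(0.0, index=B.columns),
            q=pd.Series(const, index=idx),
            separation_flag=True,
        )
    Z = pd.concat([X, B], axis=1).astype(float)
    dropped = []
    M = Z.to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(Z)), M])) < Z.shape[1] + 1:
        # drop collinear batch columns until full rank
        keep = list(X.columns)
        for c in B.columns:
            trial = Z[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(Z)), trial])) == len(keep) + 2:
                keep.append(c)
            else:
                dropped.append(c)
        Z = Z[keep]
        logger.info("OTU %s: dropped collinear batch columns %s", otu_id, dropped)
    model = LogisticRegression(
        C=1.0 / (2.0 * RIDGE_LAMBDA), solver="lbfgs", max_iter=1000
    )
    model.fit(Z.to_numpy(), ind)
    coef = pd.Series(model.coef_[0], index=Z.columns)
    zeta = pd.Series(
        [float(model.intercept_[0]), *[coef.get(c, 0.0) for c in X.columns]],
        index=cov_names,
    )
    psi = pd.Series([coef.get(c, 0.0) for c in B.columns], index=B.columns)
    eta = (
        zeta.iloc[0]
        + X.to_numpy() @ zeta.iloc[1:].to_numpy()
        + B.to_numpy() @ psi.to_numpy()
    )
    return ZeroFit(
        otu_id, zeta=zeta, psi=psi,
        q=pd.Series(_clamp(expit(eta)), index=idx),
        dropped_columns=tuple(dropped),
    )


def predict_q(fit: ZeroFit, X_row, B_row) -> float:
    """Nonzero probability for a (covariate, batch-indicator) context.

    ``B_row`` may be counterfactual — an all-zero row is the reference-batch
    context used by the stage-2 correction.
    """
    X_row = np.asarray(X_row, float)
    B_row = np.asarray(B_row, float)
    if X_row.size != fit.zeta.size - 1 or B_row.size != fit.psi.size:
        raise ValueError("dimension mismatch with fitted coefficients")
    if fit.separation_flag:
        return float(fit.q.iloc[0])
    eta = fit.zeta.iloc[0] + X_row @ fit.zeta.iloc[1:].to_numpy() + B_row @ fit.psi.to_numpy()
    return float(_clamp(expit(eta)))


def predict_q_matrix(fit: ZeroFit, X: pd.DataFrame, B: pd.DataFrame) -> np.ndarray:
    """Vectorised :func:`predict_q` over aligned covariate/indicator frames."""
    if fit.separation_flag:
        return np.full(len(X), float(fit.q.iloc[0]))
    eta = (
        fit.zeta.iloc[0]
        + X.to_numpy() @ fit.zeta.iloc[1:].to_numpy()
        + B.to_numpy() @ fit.psi.to_numpy()
    )
    return _clamp(expit(eta))


def fit_zero_model(stage1: CountTable, design: StudyDesign, reference: str) -> dict[str, ZeroFit]:
    """Fit the logistic zero model for every OTU of the stage-1 table."""
    B = batch_columns(design, reference)
    X = design.covariates
    return {
        otu: fit_zero_otu(stage1.counts[otu].to_numpy(), X, B, otu_id=otu)
        for otu in stage1.otu_ids
    }
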