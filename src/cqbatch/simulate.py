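"""Zero-inflated negative-binomial simulator with known batch effects.

The generator mirrors the correction model itself: per-OTU log-means are
sigma_j + X_i' beta_j + gamma_jg + log N_i, counts are NB with per-batch
dispersion theta_g (nonsystematic distortion), and structural zeros are
imposed afterwards with probability 1 - q_ij from a logistic model with
per-batch shifts psi_g.  A truth record carries every parameter for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CountTable, StudyDesign


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults emulate a multi-study 16S profile: a few hundred OTUs, batches
    of unequal size, log-normal library sizes around 10^4 reads, moderate
    over-dispersion, and an overall zero fraction in the 30-40% range (the
    regime where quantile-based correction is most stable).
    """

    n_per_batch: tuple = (50, 50)
    m: int = 150
    sigma_range: tuple = (-7.5, -4.0)
    beta: tuple = (0.3, 0.5)               # (continuous, binary) covariate effects
    gamma: tuple | None = None             # per-batch log-mean shifts; None = 0
    gamma_sd: float = 0.3                  # per-OTU spread around each batch shift
    gamma_alternating: bool = False        # flip the shift sign on odd OTUs
    theta_per_batch: tuple | None = None   # per-batch dispersion; None = 0.3 each
    zero_intercept: float = 0.5
    zeta: tuple = (0.3, 0.2)               # zero-model covariate effects
    psi: tuple | None = None               # per-batch zero-model shifts; None = 0
    library_size_log_mean: float = np.log(2e4)
    library_size_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.n_per_batch)
        if k < 1 or any(n < 3 for n in self.n_per_batch):
            raise ValueError("every batch needs at least 3 samples")
        if self.m < 1:
            raise ValueError("m must be positive")
        if self.gamma is None:
            self.gamma = tuple(0.0 for _ in range(k))
        if self.theta_per_batch is None:
            self.theta_per_batch = tuple(0.3 for _ in range(k))
        if self.psi is None:
            self.psi = tuple(0.0 for _ in range(k))
        if not (len(self.gamma) == len(self.theta_per_batch) == len(self.psi) == k):
            raise ValueError("gamma, theta_per_batch and psi must have one entry per batch")
        if any(t < 0 for t in self.theta_per_batch):
            raise ValueError("dispersions must be non-negative")
        if self.gamma_sd < 0:
            raise ValueError("gamma_sd must be non-negative")
        if self.library_size_log_sd < 0:
            raise ValueError("library_size_log_sd must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        # centre gamma to the sample-size-weighted sum-to-zero constraint
        n = np.asarray(self.n_per_batch, float)
        g = np.asarray(self.gamma, float)
        self.gamma = tuple(g - float(n @ g) / n.sum())

    @property
    def k_batches(self) -> int:
        return len(self.n_per_batch)

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_batch))


@dataclass
class SimTruth:
    """Generating parameters, aligned with the emitted table."""

    sigma: np.ndarray                # (m,)
    beta: np.ndarray                 # (m, 2)
    gamma: np.ndarray                # (m, k)
    theta: np.ndarray                # (k,)
    zero_intercept: float
    zeta: np.ndarray
    psi: np.ndarray                  # (k,)
    structural_zero: np.ndarray      # (n, m) bool
    batch_levels: list = field(default_factory=list)
    n_per_batch: tuple = ()

    def identifiable_gamma(self) -> np.ndarray:
        """Batch effects identifiable under an observed-library-size offset.

        The correction model offsets by the OBSERVED library size (row sum),
        which scales with the batch's total composition factor
        c_g = sum_j exp(sigma_j + gamma_jg); that common log-factor is
        absorbed by the offset and is not estimable.  Returns gamma with
        log c_g removed per batch and each OTU's row re-centred to the
        sample-size-weighted sum-to-zero constraint — the quantity a
        consistent estimator converges to.
        """
        c = np.log(np.exp(self.sigma[:, None] + self.gamma).sum(axis=0))
        adj = self.gamma - c[None, :]
        w = np.asarray(self.n_per_batch, float)
        return adj - (adj @ w / w.sum())[:, None]


def generate(config: SimConfig) -> tuple[CountTable, StudyDesign, SimTruth]:
    """Draw one synthetic study: counts, design, and the generating truth."""
    rng = np.random.default_rng(config.seed)
    k, m = config.k_batches, config.m
    batch_levels = [f"B{g+1}" for g in range(k)]
    batch = np.repeat(batch_levels, config.n_per_batch)
    n = batch.size
    sample_ids = [f"S{i+1:04d}" for i in range(n)]
    otu_ids = [f"OTU{j+1:04d}" for j in range(m)]
    codes = np.repeat(np.arange(k), config.n_per_batch)

    lib = np.exp(rng.normal(config.library_size_log_mean, config.library_size_log_sd, n))
    lib = np.maximum(np.round(lib), 100).astype(np.int64)
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, n).astype(float)
    X = np.column_stack([x1, x2])

    sigma = rng.uniform(*config.sigma_range, m)
    beta = np.tile(np.asarray(config.beta, float), (m, 1))
    # Per-OTU batch effects must change COMPOSITION, not just depth: an
    # OTU-constant shift multiplies every count in the batch, is absorbed
    # into the observed library size, and is unidentifiable under an offset
    # model.  ``gamma_alternating`` flips the shift sign on odd OTUs (exact,
    # mean-zero across OTUs -- used for parameter recovery); ``gamma_sd``
    # scatters per-OTU effects around the batch-level shift (realistic).
    # Each OTU's row keeps the sample-size-weighted sum-to-zero constraint.
    gamma = np.tile(np.asarray(config.gamma, float), (m, 1))
    if config.gamma_alternating:
        gamma[1::2] *= -1.0
    if config.gamma_sd > 0 and len(config.n_per_batch) > 1:
        gamma = gamma + rng.normal(0.0, config.gamma_sd, gamma.shape)
        w = np.asarray(config.n_per_batch, float)
        gamma -= (gamma @ w / w.sum())[:, None]
    theta = np.asarray(config.theta_per_batch, float)

    log_mu = sigma[None, :] + X @ beta.T + gamma.T[codes] + np.log(lib)[:, None]
    mu = np.exp(log_mu)

    counts = np.empty((n, m), dtype=np.int64)
    for g in range(k):
        rows = codes == g
        t = theta[g]
        if t <= 0:
            counts[rows] = rng.poisson(mu[rows])
        else:
            r = 1.0 / t
            counts[rows] = rng.negative_binomial(r, r / (r + mu[rows]))

    zeta = np.asarray(config.zeta, float)
    psi = np.asarray(config.psi, float)
    q = expit(config.zero_intercept + X @ zeta + psi[codes])
    structural = rng.random((n, m)) > q[:, None]
    counts[structural] = 0

    # guard against empty samples (possible at extreme settings)
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, 0] = 1

    table = CountTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))
    design = StudyDesign(
        batch=pd.Series(batch, index=sample_ids, name="batch"),
        covariates=pd.DataFrame({"x1": x1, "x2": x2}, index=sample_ids),
    )
    truth = SimTruth(sigma, beta, gamma, theta, config.zero_intercept,
                     zeta, psi, structural, batch_levels,
                     tuple(config.n_per_batch))
    return table, design, truth


def presets() -> dict[str, SimConfig]:
    """Named study-shaped configurations.

    ``hivrc_like`` mirrors a 4-study gut consortium (batch sizes 232, 43, 23,
    62); ``mouth_like`` mirrors a 7-plate oral study (43, 49, 56, 79, 89, 88,
    91).  Both carry systematic log-mean shifts, batch-specific dispersions
    and batch-specific zero-rate shifts, so both kinds of batch effect are
    present.
    """
    return {
        "hivrc_like": SimConfig(
            n_per_batch=(232, 43, 23, 62),
            m=200,
            gamma=(0.8, -0.5, 0.6, -0.6),
            theta_per_batch=(0.3, 0.6, 0.45, 0.55),
            psi=(0.6, -0.4, 0.3, -0.5),
        ),
        "mouth_like": SimConfig(
            n_per_batch=(43, 49, 56, 79, 89, 88, 91),
            m=200,
            gamma=(0.6, -0.4, 0.5, -0.3, 0.2, -0.5, 0.3),
            theta_per_batch=(0.3, 0.5, 0.4, 0.6, 0.35, 0.55, 0.45),
            psi=(0.4, -0.3, 0.2, -0.2, 0.3, -0.4, 0.25),
        ),
        "null": SimConfig(
            n_per_batch=(50, 50, 50),
            m=100,
        ),
    }
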