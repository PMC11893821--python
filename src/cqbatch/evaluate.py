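"""Batch-effect evaluation: beta-diversity distances, PERMANOVA R-squared,
PCoA, and the batch-labelled average silhouette.

The intended reading after a successful correction: PERMANOVA R2 for the
batch factor drops, the average silhouette of batch labels moves toward 0,
and batches intermingle in the first two PCoA axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .data import CountTable, StudyDesign

logger = logging.getLogger(__name__)

METRICS = ("bray_curtis", "aitchison", "canberra", "manhattan")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    sample_ids: list
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
            raise ValueError("distance matrix must be square and symmetric")
        if not np.allclose(np.diag(m), 0) or not np.isfinite(m).all():
            raise ValueError("distance matrix must be finite with zero diagonal")
        self.matrix = m


def clr_transform(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of (counts + pseudocount) compositions."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    z = np.log(np.asarray(counts, float) + pseudocount)
    return z - z.mean(axis=1, keepdims=True)


def distance(
    table: CountTable,
    metric: str,
    pseudocount: float = 0.5,
    relative: bool = False,
) -> DistanceMatrix:
    """Pairwise dissimilarities between samples.

    Aitchison is the Euclidean distance between CLR-transformed compositions;
    the other metrics operate on raw counts (or relative abundances when
    ``relative`` is set).  Canberra skips coordinates where both entries are
    zero, the usual convention for sparse counts.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = table.counts.to_numpy().astype(float)
    if metric == "aitchison":
        d = pdist(clr_transform(X, pseudocount), metric="euclidean")
    else:
        if relative:
            X = X / X.sum(axis=1, keepdims=True)
        scipy_name = {"bray_curtis": "braycurtis", "canberra": "canberra",
                      "manhattan": "cityblock"}[metric]
        d = pdist(X, metric=scipy_name)
    return DistanceMatrix(table.sample_ids, squareform(d), metric)


def permanova_r2(
    D: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-factor PERMANOVA (adonis-style): R2 and permutation p-value.

    R2 = SS_between / SS_total from the squared-distance decomposition
    SS_total = sum_{i<j} d_ij^2 / n and SS_within = sum over groups of the
    same quantity inside the group.  The p-value counts permuted pseudo-F
    statistics at least as large as the observed one, with the +1 correction.
    """
    labels = np.asarray(labels)
    d2 = D.matrix**2
    n = d2.shape[0]
    if labels.size != n:
        raise ValueError("labels must match the distance matrix")
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    ss_total = d2.sum() / (2.0 * n)
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: all samples identical")
    k = levels.size

    def _f_and_r2(lab):
        ss_within = 0.0
        for g in levels:
            idx = np.flatnonzero(lab == g)
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        ss_between = ss_total - ss_within
        r2 = ss_between / ss_total
        if n == k:  # no within-group degrees of freedom
            return np.inf if ss_between > 0 else 0.0, r2
        f = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf
        return f, r2

    f_obs, r2_obs = _f_and_r2(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p, _ = _f_and_r2(rng.permutation(labels))
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r2_obs), float(p)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalue_fractions: np.ndarray
    n_negative_eigenvalues: int
    truncated: bool = False


def pcoa(D: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical PCoA of the Gower-centred squared-distance matrix.

    Axes are ordered by eigenvalue; negative eigenvalues are dropped and
    counted.  When fewer positive axes exist than requested, the result is
    truncated and flagged.
    """
    if n_axes < 2:
        raise ValueError("n_axes must be >= 2")
    import warnings

    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.ordination import pcoa as skbio_pcoa

    ids = [str(s) for s in D.sample_ids]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = skbio_pcoa(SkbioDM(D.matrix, ids=ids), method="eigh")
    eig = res.eigvals.to_numpy()
    n_neg = int((eig < -1e-10).sum())
    pos = eig > 1e-12
    n_have = int(pos.sum())
    take = min(n_axes, n_have)
    coords = res.samples.iloc[:, :take].copy()
    coords.columns = [f"PC{i+1}" for i in range(take)]
    fractions = np.clip(eig, 0, None)
    fractions = fractions[:take] / fractions.sum() if fractions.sum() > 0 else fractions[:take]
    return PCoAResult(coords, fractions, n_neg, truncated=take < n_axes)


def avg_silhouette(D: DistanceMatrix, labels) -> float:
    """Mean silhouette coefficient over samples, given batch labels.

    Singleton clusters contribute 0 by convention (sklearn's behaviour).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 labels")
    sizes = pd.Series(labels).value_counts()
    if (sizes == 1).any():
        logger.info("singleton clusters present; their silhouette is 0")
    s = silhouette_samples(D.matrix, labels, metric="precomputed")
    return float(s.mean())


@dataclass
class EvaluationReport:
    """Per-metric PERMANOVA R2 / p, average silhouette, and PCoA axes."""

    per_metric: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "permanova_r2": v["permanova_r2"],
             "permanova_p": v["permanova_p"], "avg_silhouette": v["avg_silhouette"]}
            for m, v in self.per_metric.items()
        ]
        return pd.DataFrame(rows)


def evaluate_table(
    table: CountTable,
    design: StudyDesign,
    metrics=METRICS,
    n_perm: int = 999,
    seed: int = 0,
    pseudocount: float = 0.5,
    relative: bool = False,
) -> EvaluationReport:
    """Full batch-effect report for one table."""
    labels = design.batch.to_numpy()
    report = EvaluationReport()
    for metric in metrics:
        D = distance(table, metric, pseudocount=pseudocount, relative=relative)
        r2, p = permanova_r2(D, labels, n_perm=n_perm, seed=seed)
        sil = avg_silhouette(D, labels)
        ord_res = pcoa(D)
        coords = ord_res.coordinates.copy()
        coords["batch"] = labels
        report.per_metric[metric] = {
            "permanova_r2": r2,
            "permanova_p": p,
            "avg_silhouette": sil,
            "pcoa": coords,
            "eigenvalue_fractions": ord_res.eigenvalue_fractions,
        }
    return report


def evaluate_correction(
    before: CountTable,
    after: CountTable,
    design: StudyDesign,
    metrics=METRICS,
    n_perm: int = 999,
    seed: int = 0,
    **kwargs,
) -> dict[str, EvaluationReport]:
    """Reports for the uncorrected and corrected tables, same settings."""
    if before.sample_ids != after.sample_ids:
        raise ValueError("tables must be aligned")
    return {
        "before": evaluate_table(before, design, metrics, n_perm, seed, **kwargs),
        "after": evaluate_table(after, design, metrics, n_perm, seed, **kwargs),
    }
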