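"""Data-driven reference-batch selection.

The reference batch is the batch other batches are mapped onto in stage 2.
Candidates are screened for homogeneity with per-OTU pairwise Kruskal-Wallis
tests on relative abundances; among the shortlisted batches the one with the
lowest Robust CV (100 * MAD / median, no normal-consistency constant) wins.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import CountTable, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class ReferenceReport:
    """Outcome of reference selection: screening scores and the winner."""

    per_batch_homogeneity: dict[str, float]
    per_batch_robust_cv: dict[str, float]  # percent; NaN = undefined
    shortlist: list[str]
    selected: str
    forced: bool = False
    alpha: float = 0.05
    shortlist_rule: str = "top_half"

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "forced": self.forced,
            "shortlist": self.shortlist,
            "alpha": self.alpha,
            "shortlist_rule": self.shortlist_rule,
            "per_batch_homogeneity": self.per_batch_homogeneity,
            "per_batch_robust_cv": {
                g: (None if math.isnan(v) else v)
                for g, v in self.per_batch_robust_cv.items()
            },
        }


def robust_cv(values) -> float:
    """Robust coefficient of variation, 100 * MAD/median, in percent.

    MAD is the plain median absolute deviation from the median (no 1.4826
    consistency factor).  Returns NaN ("undefined") when the median is not
    positive; callers must propagate, never drop, that sentinel.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("robust_cv needs at least 3 values")
    med = float(np.median(x))
    if med <= 0:
        return float("nan")
    mad = float(np.median(np.abs(x - med)))
    return 100.0 * mad / med


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    All pooled values identical is a defined degenerate case: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def batch_homogeneity(table: CountTable, design: StudyDesign, alpha: float = 0.05) -> dict[str, float]:
    """Fraction of non-significant pairwise per-OTU comparisons per batch.

    For every unordered batch pair and every OTU, a Kruskal-Wallis test
    compares the two batches' relative abundances (zeros included).  A batch's
    homogeneity is the fraction of its (OTU, other-batch) comparisons with
    p >= alpha; values near 1 mean the batch is distributionally unremarkable.
    """
    levels = design.batch_levels
    rel = table.relative_abundance().to_numpy()
    members = {g: (design.batch == g).to_numpy() for g in levels}
    nonsig = {g: 0 for g in levels}
    total = {g: 0 for g in levels}
    for g, h in itertools.combinations(levels, 2):
        xg, xh = rel[members[g]], rel[members[h]]
        for j in range(rel.shape[1]):
            _, p = kruskal_wallis([xg[:, j], xh[:, j]])
            ok = int(p >= alpha)
            nonsig[g] += ok
            nonsig[h] += ok
            total[g] += 1
            total[h] += 1
    return {g: nonsig[g] / total[g] for g in levels}


def _batch_robust_cv(table: CountTable, design: StudyDesign, g: str) -> float:
    """Median across OTUs of the Robust CV of the batch's nonzero counts.

    OTUs with fewer than 3 nonzero values in the batch are skipped; NaN when
    no OTU qualifies or every per-OTU Robust CV is undefined.
    """
    sub = table.counts.loc[(design.batch == g).to_numpy()].to_numpy()
    cvs = []
    for j in range(sub.shape[1]):
        nz = sub[:, j][sub[:, j] > 0]
        if nz.size < 3:
            continue
        cv = robust_cv(nz)
        if not math.isnan(cv):
            cvs.append(cv)
    return float(np.median(cvs)) if cvs else float("nan")


def select_reference(
    table: CountTable,
    design: StudyDesign,
    alpha: float = 0.05,
    shortlist_rule: str = "top_half",
    homogeneity_threshold: float = 0.5,
    force: str | None = None,
) -> ReferenceReport:
    """Pick the reference batch: homogeneity shortlist, then lowest Robust CV.

    ``shortlist_rule="top_half"`` keeps batches at or above the median
    homogeneity; ``"threshold"`` keeps those at or above
    ``homogeneity_threshold``.  Ties on Robust CV break toward the larger
    batch, then the lexicographically smaller label.  ``force`` bypasses
    selection entirely (echoed via ``forced=True``).
    """
    levels = design.batch_levels
    if force is not None:
        if force not in levels:
            raise ValueError(f"forced reference {force!r} is not a batch label")
        return ReferenceReport({}, {}, [force], force, forced=True,
                               alpha=alpha, shortlist_rule="forced")
    if len(levels) < 2:
        raise ValueError("reference selection needs at least 2 batches")
    if shortlist_rule not in ("top_half", "threshold"):
        raise ValueError(f"unknown shortlist rule {shortlist_rule!r}")

    homog = batch_homogeneity(table, design, alpha=alpha)
    cut = (float(np.median(list(homog.values())))
           if shortlist_rule == "top_half" else homogeneity_threshold)
    shortlist = [g for g in levels if homog[g] >= cut]
    if not shortlist:  # threshold rule can empty the list; fall back to best
        shortlist = [max(levels, key=lambda g: homog[g])]
    cvs = {g: _batch_robust_cv(table, design, g) for g in levels}
    defined = [g for g in shortlist if not math.isnan(cvs[g])]
    if not defined:
        raise ValueError(
            "Robust CV undefined for every shortlisted batch; "
            "choose a reference manually (force=...)"
        )
    sizes = design.batch_sizes()
    selected = min(defined, key=lambda g: (cvs[g], -sizes[g], g))
    logger.info("selected reference batch %r (robust CV %.2f%%)", selected, cvs[selected])
    return ReferenceReport(homog, cvs, shortlist, selected,
                           alpha=alpha, shortlist_rule=shortlist_rule)
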