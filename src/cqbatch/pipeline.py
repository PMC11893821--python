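"""End-to-end orchestration: read -> align -> filter -> reference ->
stage 1 (NB) -> stage 2 (zero model + CQR) -> evaluate, with provenance."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cqr as cqr_mod
from . import evaluate as eval_mod
from . import nb as nb_mod
from . import zeros as zero_mod
from .data import (
    CorrectionResult,
    CountTable,
    StudyDesign,
    align,
    filter_otus,
    reattach_otus,
)
from .reference import select_reference

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings for one correction run; echoed into provenance."""

    reference: str = "auto"          # "auto" or a batch label
    k: int = cqr_mod.DEFAULT_K
    mode: str = "composite"
    alpha: float = 0.05
    shortlist_rule: str = "top_half"
    min_prevalence: float = 0.0
    min_nonzero_per_batch: int = 3
    pseudocount: float = 0.5
    n_perm: int = 999
    seed: int = 0
    stage: str = "full"              # "full" | "nb"
    stochastic_map: bool = False     # jittered CDF levels in stage 1
    stochastic_zeros: bool = False   # uniform zero levels in stage 2
    metrics: tuple = eval_mod.METRICS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        return d


def correct(
    table: CountTable,
    design: StudyDesign,
    config: RunConfig | None = None,
) -> CorrectionResult:
    """Run both correction stages on an already-loaded table and design."""
    config = config or RunConfig()
    table, design = align(table, design)
    work, excluded = filter_otus(
        table, design,
        min_prevalence=config.min_prevalence,
        min_nonzero_per_batch=config.min_nonzero_per_batch,
    )

    if config.reference == "auto":
        report = select_reference(work, design, alpha=config.alpha,
                                  shortlist_rule=config.shortlist_rule)
    else:
        report = select_reference(work, design, force=config.reference)
    reference = report.selected
    design.reference_batch = reference

    stage1_work, nb_fits = nb_mod.correct_systematic(
        work, design, stochastic_map=config.stochastic_map, seed=config.seed)
    stage1 = reattach_otus(stage1_work, table, excluded)
    uncorrectable = {o for o, f in nb_fits.items() if f.uncorrectable}

    provenance = {
        "config": config.to_dict(),
        "reference_batch": reference,
        "reference_report": report.to_dict(),
        "n_samples": table.n_samples,
        "n_otus": table.n_otus,
        "otus_uncorrected": sorted(set(excluded) | uncorrectable),
    }

    if config.stage == "nb":
        return CorrectionResult(stage1, stage1, nb_fits, {}, {}, provenance)

    tau_grid = cqr_mod.default_tau_grid(config.k)
    zero_fits = zero_mod.fit_zero_model(stage1_work, design, reference)
    cqr_fits = cqr_mod.fit_cqr_model(stage1_work, design, reference,
                                     tau_grid=tau_grid, mode=config.mode)
    corrected_work = cqr_mod.correct_nonsystematic(
        stage1_work, design, zero_fits, cqr_fits, reference,
        uncorrectable=uncorrectable,
        stochastic_zeros=config.stochastic_zeros, seed=config.seed,
    )
    corrected = reattach_otus(corrected_work, stage1, excluded)
    return CorrectionResult(corrected, stage1, nb_fits, zero_fits, cqr_fits, provenance)


def run_pipeline(
    table: CountTable,
    design: StudyDesign,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[CorrectionResult, dict[str, eval_mod.EvaluationReport]]:
    """Correct and evaluate; optionally write tables, reports and provenance."""
    config = config or RunConfig()
    table, design = align(table, design)
    result = correct(table, design, config)
    reports = eval_mod.evaluate_correction(
        table, result.corrected, design,
        metrics=config.metrics, n_perm=config.n_perm, seed=config.seed,
        pseudocount=config.pseudocount,
    )
    if outdir is not None:
        write_outputs(result, reports, outdir)
    return result, reports


def fit_summary(result: CorrectionResult) -> pd.DataFrame:
    """Per-OTU stage-1/stage-2 parameter table (one row per OTU)."""
    rows = []
    for otu, f in result.nb_fits.items():
        row = {"otu": otu, "sigma": f.sigma, "theta_star": f.theta_star,
               "converged": f.converged, "uncorrectable": f.uncorrectable}
        for g, v in f.gamma.items():
            row[f"gamma[{g}]"] = v
        for g, v in f.theta.items():
            row[f"theta[{g}]"] = v
        zf = result.zero_fits.get(otu)
        if zf is not None:
            for name, v in zf.zeta.items():
                row[f"zeta[{name}]"] = v
            for name, v in zf.psi.items():
                row[f"psi[{name}]"] = v
            row["separation"] = zf.separation_flag
        cf = result.cqr_fits.get(otu)
        if cf is not None:
            row["cqr_mode"] = cf.mode
            row["cqr_fallback"] = cf.fallback
            row["cqr_objective"] = cf.objective
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result, reports, outdir) -> None:
    from .data import write_count_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(result.corrected, outdir / "corrected.tsv")
    write_count_table(result.stage1_table, outdir / "stage1.tsv")
    fit_summary(result).to_csv(outdir / "fit_summary.tsv", sep="\t", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
    if reports:
        frames = []
        for which, rep in reports.items():
            df = rep.to_frame()
            df.insert(0, "table", which)
            frames.append(df)
            for metric, entry in rep.per_metric.items():
                entry["pcoa"].to_csv(outdir / f"pcoa_{which}_{metric}.tsv", sep="\t")
        pd.concat(frames).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
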