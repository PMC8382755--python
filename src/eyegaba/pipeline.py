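"""End-to-end convenience layer: keypress streams + metabolite tables in,
fitted cohort model out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import dominance as dom_mod
from . import mrs, rivalry
from .cohort import AnalysisConfig, CohortAnalysis, CohortAnalysisResults


def compute_dominance_table(
    runs_by_subject: dict,
    min_duration: float = 0.200,
    include_censored: bool = False,
    tie_break: str | None = None,
):
    """Parse and preprocess each subject's runs and summarise eye dominance.

    Returns ``(table, preprocessed)`` where ``preprocessed`` maps subject to
    the list of :class:`~eyegaba.rivalry.PreprocessedPhases` (useful for
    pooled-histogram reporting).
    """
    results = []
    preprocessed: dict[str, list] = {}
    for sid, runs in runs_by_subject.items():
        pps = [rivalry.preprocess_run(r, min_duration=min_duration) for r in runs]
        preprocessed[sid] = pps
        results.append(
            dom_mod.compute_eye_dominance(
                sid, pps, include_censored=include_censored, tie_break=tie_break
            )
        )
    return dom_mod.dominance_table(results), preprocessed


def build_levels(
    metab: pd.DataFrame,
    tissue: pd.DataFrame,
    references=("GABA:H2O", "GABA:tCr"),
    alpha: float = 0.5,
    crlb_max: float = 30.0,
) -> pd.DataFrame:
    """Corrected levels for the requested referencing routes, concatenated."""
    parts = []
    for ref in references:
        mode = "water" if ref.endswith(":H2O") else "tCr"
        parts.append(
            mrs.correct_metabolite_table(
                metab, tissue=tissue, mode=mode, alpha=alpha, crlb_max=crlb_max
            )
        )
    return pd.concat(parts, ignore_index=True)


@dataclass
class PipelineResult:
    dominance: pd.DataFrame
    levels: pd.DataFrame
    results: CohortAnalysisResults
    preprocessed: dict


def analyze(
    runs_by_subject: dict,
    metab: pd.DataFrame,
    tissue: pd.DataFrame,
    bold: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    min_duration: float = 0.200,
    include_censored: bool = False,
    alpha_tissue: float = 0.5,
) -> PipelineResult:
    """Run the whole chain: parse -> dominance -> corrections -> battery."""
    config = config or AnalysisConfig()
    dom, pps = compute_dominance_table(
        runs_by_subject, min_duration=min_duration, include_censored=include_censored
    )
    levels = build_levels(
        metab,
        tissue,
        references=config.references,
        alpha=alpha_tissue,
        crlb_max=config.crlb_max,
    )
    results = CohortAnalysis(dom, levels, bold, config).fit()
    return PipelineResult(dom, levels, results, pps)
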