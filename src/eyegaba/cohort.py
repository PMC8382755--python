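"""Cohort-level model relating eye dominance to interocular GABA.

The central question is whether individuals with stronger sensory eye
dominance (larger EDI) show a larger interocular difference in GABAergic
inhibition.  :class:`CohortAnalysis` is the model object: it is built from the
per-subject dominance table and the corrected metabolite levels (plus optional
per-eye %BOLD changes), applies the mixed-fraction participant screen, and its
:meth:`~CohortAnalysis.fit` runs the full inferential battery:

* paired DE vs NDE comparisons (median phase durations; GABA per reference);
* EDI x interocular GABA for each reference;
* EDI x per-eye (DE, NDE) GABA and EDI x resting GABA;
* EDI x interocular delta-GABA (checkerboard > fixation control);
* EDI x interocular %BOLD (when BOLD data are supplied);
* suppression x resting GABA.

Each test is normality-gated (Shapiro-Wilk): correlations use Spearman with an
exact-distribution p when either variable fails the gate and Pearson otherwise;
paired tests use the paired t or Wilcoxon signed-rank.  Alpha is 0.05,
uncorrected; the result object reports the number of tests so users can apply
their own correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import interocular as io_metric
from .exceptions import DegenerateInputError, InsufficientDataError, PairingError
from .inference import (
    CorrelationResult,
    PairedComparisonResult,
    normality_gate,
    paired_compare,
    pearson_corr,
    spearman_exact,
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the cohort analysis.

    ``mixed_screen_pct`` is this package's default participant screen (percent
    of reported time in the mixed percept at or above which a subject is
    excluded); ``seed`` feeds every Monte-Carlo path and is embedded in the
    report.
    """

    alpha: float = 0.05
    gate_alpha: float = 0.05
    mixed_screen_pct: float = 50.0
    crlb_max: float = 30.0
    seed: int | None = None
    references: tuple = ("GABA:H2O", "GABA:tCr")


class CohortAnalysis:
    """Model object for the eye-dominance / GABA cohort battery.

    Parameters
    ----------
    dominance : frame with columns subject, d_de, d_nde, edi_pct, suppression,
        mixed_fraction_pct (from :func:`eyegaba.dominance.dominance_table`).
    levels : long frame subject, condition, block, measure, level with
        conditions DE/NDE/rest (from
        :func:`eyegaba.mrs.correct_metabolite_table`, one or both references
        concatenated).
    bold : optional frame subject, condition, pbold_change (externally
        computed per-eye %BOLD changes).
    """

    def __init__(
        self,
        dominance: pd.DataFrame,
        levels: pd.DataFrame | None = None,
        bold: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.dominance = dominance.copy()
        self.levels = None if levels is None else levels.copy()
        self.bold = None if bold is None else bold.copy()
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(
        cls,
        dominance_csv,
        levels_csv=None,
        bold_csv=None,
        config: AnalysisConfig | None = None,
    ) -> "CohortAnalysis":
        dom = pd.read_csv(dominance_csv)
        lev = pd.read_csv(levels_csv) if levels_csv is not None else None
        bold = pd.read_csv(bold_csv) if bold_csv is not None else None
        return cls(dom, lev, bold, config)

    # -- internals ---------------------------------------------------------

    def _screen(self):
        dom = self.dominance
        excluded = dom.loc[
            dom["mixed_fraction_pct"] >= self.config.mixed_screen_pct, "subject"
        ].tolist()
        kept = dom[~dom["subject"].isin(excluded)].reset_index(drop=True)
        return kept, excluded

    def _correlate(self, x, y, name_x, name_y) -> CorrelationResult:
        gx = normality_gate(x, alpha=self.config.gate_alpha)
        gy = normality_gate(y, alpha=self.config.gate_alpha)
        if "nonparametric" in (gx.decision, gy.decision):
            return spearman_exact(x, y, name_x, name_y, seed=self.config.seed)
        return pearson_corr(x, y, name_x, name_y)

    def fit(self) -> "CohortAnalysisResults":
        cfg = self.config
        dom, excluded = self._screen()
        if len(dom) < 3:
            raise InsufficientDataError(
                f"only {len(dom)} subjects survive the mixed-fraction screen"
            )
        subjects = set(dom["subject"])
        rows: list[dict] = []
        notes: list[str] = []
        n_undefined = 0

        def corr_row(frame_y, name_y, label):
            merged = dom[["subject", "edi_pct"]].merge(frame_y, on="subject").dropna()
            self._add_corr(rows, notes, merged, "edi_pct", "EDI", name_y, label)

        def _levels(measure, condition, block="all"):
            lev = self.levels
            sel = lev[
                (lev["measure"] == measure)
                & (lev["condition"] == condition)
                & (lev["block"] == block)
                & lev["subject"].isin(subjects)
            ]
            return sel[["subject", "level"]]

        # paired: DE vs NDE median phase durations
        rows.append(
            self._paired_row(
                "d_DE vs d_NDE median phase duration",
                dom["d_de"].to_numpy(),
                dom["d_nde"].to_numpy(),
            )
        )

        if self.levels is not None:
            available = set(self.levels["measure"])
            for ref in cfg.references:
                if ref not in available:
                    continue
                de = _levels(ref, "DE").rename(columns={"level": "de"})
                nde = _levels(ref, "NDE").rename(columns={"level": "nde"})
                pair = de.merge(nde, on="subject").dropna()
                if len(pair) >= 3:
                    rows.append(
                        self._paired_row(
                            f"DE vs NDE {ref}",
                            pair["de"].to_numpy(),
                            pair["nde"].to_numpy(),
                        )
                    )
                # EDI x interocular
                inter = io_metric.interocular_table(
                    self.levels[self.levels["subject"].isin(subjects)]
                )
                sel = inter[inter["measure"] == ref][["subject", "index"]]
                corr_row(sel, f"interocular {ref}", f"EDI ~ interocular {ref}")
                # EDI x per-eye levels
                for cond in ("DE", "NDE"):
                    corr_row(
                        _levels(ref, cond).rename(columns={"level": "index"}),
                        f"{cond} {ref}",
                        f"EDI ~ {cond} {ref}",
                    )
                # EDI x resting
                rest = _levels(ref, "rest").rename(columns={"level": "index"})
                if len(rest) >= 3:
                    corr_row(rest, f"resting {ref}", f"EDI ~ resting {ref}")
                    # suppression x resting
                    merged = (
                        dom[["subject", "suppression"]]
                        .merge(rest, on="subject")
                        .dropna()
                    )
                    self._add_corr(
                        rows,
                        notes,
                        merged,
                        "suppression",
                        "suppression",
                        f"resting {ref}",
                        f"suppression ~ resting {ref}",
                    )
                # EDI x interocular delta (checkerboard > fixation control)
                delta = io_metric.delta_interocular_table(
                    self.levels[self.levels["subject"].isin(subjects)]
                )
                dsel = delta[delta["measure"] == f"{ref}:delta"]
                n_undefined += int((~dsel["defined"]).sum())
                corr_row(
                    dsel[["subject", "index"]],
                    f"interocular d{ref}",
                    f"EDI ~ interocular delta {ref}",
                )

        if self.bold is not None:
            binter = io_metric.bold_interocular_table(
                self.bold[self.bold["subject"].isin(subjects)]
            )
            n_undefined += int((~binter["defined"]).sum())
            corr_row(
                binter[["subject", "index"]],
                "interocular %BOLD",
                "EDI ~ interocular %BOLD",
            )

        table = pd.DataFrame(rows)
        table["significant"] = table["p"] < cfg.alpha
        return CohortAnalysisResults(
            table=table,
            excluded_subjects=excluded,
            n_subjects=len(dom),
            n_undefined_ratios=n_undefined,
            notes=notes,
            config=cfg,
        )

    def _paired_row(self, label: str, a, b) -> dict:
        res: PairedComparisonResult = paired_compare(
            a, b, gate_alpha=self.config.gate_alpha
        )
        return {
            "analysis": label,
            "method": res.method,
            "stat": res.statistic,
            "p": res.p,
            "p_method": "exact" if res.method == "wilcoxon_signed_rank" else "approximate",
            "n": res.n,
        }

    def _add_corr(self, rows, notes, merged, xcol, name_x, name_y, label):
        if len(merged) < 3:
            notes.append(f"{label}: skipped, only {len(merged)} complete cases")
            return
        x = merged[xcol].to_numpy(dtype=float)
        y = merged["index"].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degeneracy warning handled below
                res = self._correlate(x, y, name_x, name_y)
        except DegenerateInputError:
            notes.append(f"{label}: skipped, zero variance in a variable")
            return
        rows.append(
            {
                "analysis": label,
                "method": res.method,
                "stat": res.r,
                "p": res.p,
                "p_method": res.p_method,
                "n": res.n,
            }
        )


@dataclass
class CohortAnalysisResults:
    """Fitted cohort battery: one row per analysis plus inclusion accounting."""

    table: pd.DataFrame
    excluded_subjects: list
    n_subjects: int
    n_undefined_ratios: int
    notes: list = field(default_factory=list)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    @property
    def n_tests(self) -> int:
        return len(self.table)

    def row(self, analysis: str) -> pd.Series:
        sel = self.table[self.table["analysis"] == analysis]
        if sel.empty:
            raise KeyError(f"no analysis named {analysis!r}")
        return sel.iloc[0]

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Cohort analysis: eye dominance x interocular GABA",
            "=" * 58,
            f"subjects analysed: {self.n_subjects}"
            + (f"  (excluded by mixed-percept screen: {self.excluded_subjects})"
               if self.excluded_subjects else ""),
            f"alpha = {cfg.alpha} (uncorrected), {self.n_tests} tests run",
            f"mixed-percept screen >= {cfg.mixed_screen_pct}% of reported time",
            f"undefined interocular ratios excluded pairwise: {self.n_undefined_ratios}",
            f"seed: {cfg.seed}",
            "-" * 58,
        ]
        hdr = f"{'analysis':<38}{'method':<22}{'stat':>8}{'p':>9}{'n':>4}"
        lines.append(hdr)
        for _, r in self.table.iterrows():
            star = " *" if r["significant"] else ""
            lines.append(
                f"{r['analysis']:<38}{r['method']:<22}{r['stat']:>8.3f}"
                f"{r['p']:>9.4f}{r['n']:>4}{star}"
            )
        if self.notes:
            lines.append("-" * 58)
            lines.extend(self.notes)
        return "\n".join(lines)


def run_cohort_analysis(
    dominance: pd.DataFrame,
    levels: pd.DataFrame | None = None,
    bold: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> CohortAnalysisResults:
    """Functional wrapper: build :class:`CohortAnalysis` and fit it."""
    if levels is not None and dominance["subject"].isin(levels["subject"]).sum() == 0:
        raise PairingError("dominance and levels tables share no subjects")
    return CohortAnalysis(dominance, levels, bold, config).fit()
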