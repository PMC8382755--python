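"""Metabolite tissue corrections, referencing and quality screens.

Operates on tabulated spectral-fit outputs (one concentration estimate per
subject x viewing condition x block, with a Cramér-Rao lower bound in percent)
plus per-subject voxel tissue fractions.  Two referencing routes are provided:

``water``
    The water-scaled estimate is corrected for CSF partial volume,
    M / (1 - f_CSF), because CSF contributes no metabolite signal, and then
    alpha-corrected for grey/white tissue composition,

        c_corr = c / (f_GM + alpha * f_WM) * (mu_GM + alpha * mu_WM) / (mu_GM + mu_WM),

    where alpha (default 0.5) is the assumed white/grey metabolite concentration
    ratio and mu_GM, mu_WM are the group-mean tissue fractions.  The result is a
    "GABA:H2O"-style level normalised to the group tissue composition.

``tCr``
    A plain ratio of the metabolite to total creatine from the same voxel and
    time; referencing to tCr already controls for tissue composition and CSF,
    so no further correction is applied.

No relaxation (T1/T2) correction is applied anywhere.  The cohort-level
quality screen drops a metabolite when its mean CRLB across participants
exceeds a threshold (default 30%); a per-spectrum mode is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
)

TISSUE_TOL = 1e-6


@dataclass(frozen=True)
class TissueFractions:
    """Voxel grey-matter / white-matter / CSF composition for one subject."""

    subject_id: str
    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self):
        for name, f in (("f_gm", self.f_gm), ("f_wm", self.f_wm), ("f_csf", self.f_csf)):
            if not 0 <= f <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {f}")
        if abs(self.f_gm + self.f_wm + self.f_csf - 1.0) > TISSUE_TOL:
            raise ParameterError(
                "tissue fractions must sum to 1 "
                f"(got {self.f_gm + self.f_wm + self.f_csf})"
            )


@dataclass(frozen=True)
class GroupTissueMeans:
    """Group-mean GM and WM fractions entering the alpha correction."""

    mu_gm: float
    mu_wm: float

    def __post_init__(self):
        for name, m in (("mu_gm", self.mu_gm), ("mu_wm", self.mu_wm)):
            if not 0 < m <= 1:
                raise ParameterError(f"{name} must be in (0, 1], got {m}")


@dataclass(frozen=True)
class MetaboliteEstimate:
    """One quantified metabolite level with quality metadata."""

    subject_id: str
    metabolite: str
    condition: str  # "DE" | "NDE" | "rest"
    block: str  # "all" | "checkerboard" | "fixation"
    value: float
    crlb_pct: float
    reference: str = "water"
    quality: dict | None = None

    def __post_init__(self):
        if not self.value > 0:
            raise ParameterError(f"metabolite value must be positive, got {self.value}")
        if self.crlb_pct < 0:
            raise ParameterError(f"crlb_pct must be >= 0, got {self.crlb_pct}")


def csf_correct(m: float, f_csf: float):
    """CSF partial-volume correction M / (1 - f_CSF)."""
    if np.any(np.asarray(f_csf) >= 1) or np.any(np.asarray(f_csf) < 0):
        raise ParameterError(f"f_csf must be in [0, 1), got {f_csf}")
    if np.any(np.asarray(m) <= 0):
        raise ParameterError("metabolite value must be positive")
    return m / (1.0 - f_csf)


def alpha_correct(
    c_meas,
    f: TissueFractions | tuple,
    mu: GroupTissueMeans,
    alpha: float = 0.5,
):
    """Grey/white tissue-composition correction normalised to the group mean.

    ``f`` may be a :class:`TissueFractions` or a ``(f_gm, f_wm)`` pair; the
    fractions are used as given (no renormalisation after CSF removal — CSF is
    handled solely by :func:`csf_correct`).
    """
    if alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {alpha}")
    f_gm, f_wm = (f.f_gm, f.f_wm) if isinstance(f, TissueFractions) else (f[0], f[1])
    denom = f_gm + alpha * f_wm
    if np.any(np.asarray(denom) <= 0):
        raise DegenerateInputError(
            f"degenerate voxel: f_gm + alpha*f_wm = {denom} is not positive"
        )
    return np.asarray(c_meas) / denom * (mu.mu_gm + alpha * mu.mu_wm) / (mu.mu_gm + mu.mu_wm)


def reference_metabolite(
    value: float,
    reference_value: float | None,
    f: TissueFractions | None,
    mu: GroupTissueMeans | None,
    mode: str = "water",
    alpha: float = 0.5,
) -> float:
    """Referenced metabolite level for a single estimate.

    ``mode="water"``: ``value`` is the water-scaled estimate; apply the CSF then
    the alpha correction (needs ``f`` and ``mu``).  ``mode="tCr"``: plain ratio
    ``value / reference_value`` with no tissue correction.
    """
    if mode == "water":
        if f is None or mu is None:
            raise ConfigurationError(
                "water referencing requires tissue fractions and group means"
            )
        return float(alpha_correct(csf_correct(value, f.f_csf), f, mu, alpha=alpha))
    if mode == "tCr":
        if reference_value is None or reference_value <= 0:
            raise ParameterError("tCr referencing requires a positive tCr value")
        return value / reference_value
    raise ParameterError(f"mode must be 'water' or 'tCr', got {mode!r}")


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean.

    Scale invariant: CoV(k*x) == CoV(x) for k > 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ParameterError("CoV needs at least two measurements")
    mean = arr.mean()
    if mean == 0:
        raise DegenerateInputError("CoV undefined for zero-mean series")
    return float(arr.std(ddof=1) / mean)


def group_tissue_means(tissue: pd.DataFrame) -> GroupTissueMeans:
    """Group-mean GM/WM fractions from a tissue table (columns f_gm, f_wm)."""
    return GroupTissueMeans(float(tissue["f_gm"].mean()), float(tissue["f_wm"].mean()))


def crlb_screen(
    metab: pd.DataFrame, threshold_pct: float = 30.0, per_spectrum: bool = False
) -> pd.DataFrame:
    """Cohort-level detectability screen on the Cramér-Rao lower bound.

    By default a metabolite is excluded when its mean CRLB across all its
    estimates exceeds ``threshold_pct``; with ``per_spectrum=True`` individual
    estimates are flagged instead.  Returns a frame with columns
    ``metabolite, mean_crlb_pct, included`` (plus ``subject`` per spectrum).
    """
    if per_spectrum:
        out = metab[["subject", "metabolite", "crlb_pct"]].copy()
        out["included"] = out["crlb_pct"] <= threshold_pct
        return out
    g = metab.groupby("metabolite")["crlb_pct"].mean().reset_index()
    g = g.rename(columns={"crlb_pct": "mean_crlb_pct"})
    g["included"] = g["mean_crlb_pct"] <= threshold_pct
    return g


def correct_metabolite_table(
    metab: pd.DataFrame,
    tissue: pd.DataFrame | None = None,
    mode: str = "water",
    alpha: float = 0.5,
    mu: GroupTissueMeans | None = None,
    crlb_max: float = 30.0,
    tcr_name: str = "tCr",
    renormalise_csf: bool = False,
) -> pd.DataFrame:
    """Apply the quality screen and the chosen referencing route to a cohort
    metabolite table.

    Parameters
    ----------
    metab : frame with columns subject, condition, block, metabolite, value,
        crlb_pct, reference (water-scaled spectral-fit estimates).
    tissue : frame with columns subject, f_gm, f_wm, f_csf (water mode only).
    mu : group tissue means; computed from ``tissue`` when omitted.
    renormalise_csf : alternative reading of the alpha correction in which the
        GM/WM fractions are renormalised to exclude CSF first; off by default.

    Returns
    -------
    Long frame ``subject, condition, block, metabolite, measure, level`` where
    measure is e.g. ``"GABA:H2O"`` or ``"GABA:tCr"``.
    """
    screen = crlb_screen(metab, threshold_pct=crlb_max)
    keep = set(screen.loc[screen["included"], "metabolite"])
    df = metab[metab["metabolite"].isin(keep)].copy()

    if mode == "water":
        if tissue is None:
            raise ConfigurationError("water mode requires a tissue-fraction table")
        if mu is None:
            mu = group_tissue_means(tissue)
        df = df.merge(tissue[["subject", "f_gm", "f_wm", "f_csf"]], on="subject")
        f_gm = df["f_gm"].to_numpy(dtype=float)
        f_wm = df["f_wm"].to_numpy(dtype=float)
        f_csf = df["f_csf"].to_numpy(dtype=float)
        if renormalise_csf:
            f_gm = f_gm / (f_gm + f_wm)
            f_wm = 1.0 - f_gm
        level = csf_correct(df["value"].to_numpy(dtype=float), f_csf)
        level = alpha_correct(level, (f_gm, f_wm), mu, alpha=alpha)
        out = df[["subject", "condition", "block", "metabolite"]].copy()
        out["measure"] = out["metabolite"] + ":H2O"
        out["level"] = level
        return out.reset_index(drop=True)

    if mode == "tCr":
        tcr = df[df["metabolite"] == tcr_name][
            ["subject", "condition", "block", "value"]
        ].rename(columns={"value": "tcr_value"})
        if tcr.empty:
            raise ConfigurationError(f"no {tcr_name!r} rows to reference against")
        num = df[df["metabolite"] != tcr_name]
        out = num.merge(tcr, on=["subject", "condition", "block"])
        out["measure"] = out["metabolite"] + ":tCr"
        out["level"] = out["value"] / out["tcr_value"]
        return out[
            ["subject", "condition", "block", "metabolite", "measure", "level"]
        ].reset_index(drop=True)

    raise ParameterError(f"mode must be 'water' or 'tCr', got {mode!r}")
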