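"""Interocular difference metrics.

For any per-eye neural response N (a referenced GABA level, a %BOLD change),
the interocular metric is the fractional difference between viewing conditions:

    interocular N = (N_DE - N_NDE) / N_NDE,

positive when the response is larger under dominant-eye viewing.  The metric is
scale invariant, so it does not depend on the referencing route.

The main fMRS levels are computed across both stimulus blocks (``block="all"``).
The stimulus-contrast control variant first forms the per-eye block difference
delta = checkerboard - fixation and then applies the same metric to the pair of
deltas; a non-positive delta for the non-dominant eye makes the ratio undefined
and the subject is flagged (and later excluded pairwise) rather than silently
dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ParameterError, PairingError


def interocular_index(n_de: float, n_nde: float, allow_signed: bool = False) -> float:
    """(N_DE - N_NDE) / N_NDE.  Levels must be positive unless
    ``allow_signed=True`` (used by the block-difference variant); a
    non-positive denominator always raises."""
    if not allow_signed and (n_de <= 0 or n_nde <= 0):
        raise ParameterError(
            f"levels must be positive (got N_DE={n_de}, N_NDE={n_nde}); "
            "signed inputs are only accepted via allow_signed"
        )
    if n_nde <= 0:
        raise ParameterError(f"undefined ratio: N_NDE={n_nde} is not positive")
    return (n_de - n_nde) / n_nde


def delta_condition(checkerboard: float, fixation: float) -> float:
    """Per-eye stimulus-contrast difference checkerboard - fixation."""
    return checkerboard - fixation


def interocular_table(levels: pd.DataFrame, block: str = "all") -> pd.DataFrame:
    """Per-subject interocular metric from a corrected-levels frame.

    ``levels`` has columns subject, condition, block, measure, level (from
    :func:`eyegaba.mrs.correct_metabolite_table`).  Returns subject, measure,
    n_de, n_nde, index.
    """
    df = levels[levels["block"] == block]
    wide = df.pivot_table(
        index=["subject", "measure"], columns="condition", values="level"
    ).reset_index()
    if "DE" not in wide.columns or "NDE" not in wide.columns:
        raise PairingError("levels table lacks paired DE/NDE conditions")
    wide = wide.dropna(subset=["DE", "NDE"])
    out = wide[["subject", "measure"]].copy()
    out["n_de"] = wide["DE"].to_numpy()
    out["n_nde"] = wide["NDE"].to_numpy()
    out["index"] = [
        interocular_index(a, b) for a, b in zip(out["n_de"], out["n_nde"])
    ]
    return out


def delta_interocular_table(levels: pd.DataFrame) -> pd.DataFrame:
    """Interocular metric on per-eye checkerboard>fixation differences.

    Output columns: subject, measure (suffixed ``:delta``), n_de, n_nde
    (the per-eye deltas), index, defined.  Subjects whose non-dominant-eye
    delta is not positive get ``defined=False`` and a NaN index; callers drop
    them pairwise and report the count.
    """
    df = levels[levels["block"].isin(["checkerboard", "fixation"])]
    wide = df.pivot_table(
        index=["subject", "measure", "condition"], columns="block", values="level"
    ).reset_index()
    wide = wide.dropna(subset=["checkerboard", "fixation"])
    wide["delta"] = delta_condition(
        wide["checkerboard"].to_numpy(), wide["fixation"].to_numpy()
    )
    paired = wide.pivot_table(
        index=["subject", "measure"], columns="condition", values="delta"
    ).reset_index()
    if "DE" not in paired.columns or "NDE" not in paired.columns:
        raise PairingError("delta levels lack paired DE/NDE conditions")
    paired = paired.dropna(subset=["DE", "NDE"])
    out = paired[["subject", "measure"]].copy()
    out["measure"] = out["measure"] + ":delta"
    out["n_de"] = paired["DE"].to_numpy()
    out["n_nde"] = paired["NDE"].to_numpy()
    defined = out["n_nde"].to_numpy() > 0
    idx = np.full(len(out), np.nan)
    idx[defined] = (out["n_de"].to_numpy()[defined] - out["n_nde"].to_numpy()[defined]) / out[
        "n_nde"
    ].to_numpy()[defined]
    out["index"] = idx
    out["defined"] = defined
    return out


def bold_interocular_table(bold: pd.DataFrame, measure: str = "%BOLD") -> pd.DataFrame:
    """Interocular metric on externally computed per-eye %BOLD changes.

    ``bold`` has columns subject, condition (DE/NDE), pbold_change.
    """
    wide = bold.pivot_table(
        index="subject", columns="condition", values="pbold_change"
    ).reset_index()
    if "DE" not in wide.columns or "NDE" not in wide.columns:
        raise PairingError("BOLD table lacks paired DE/NDE conditions")
    wide = wide.dropna(subset=["DE", "NDE"])
    out = wide[["subject"]].copy()
    out["measure"] = measure
    out["n_de"] = wide["DE"].to_numpy()
    out["n_nde"] = wide["NDE"].to_numpy()
    defined = out["n_nde"].to_numpy() > 0
    idx = np.full(len(out), np.nan)
    idx[defined] = (out["n_de"].to_numpy()[defined] - out["n_nde"].to_numpy()[defined]) / out[
        "n_nde"
    ].to_numpy()[defined]
    out["index"] = idx
    out["defined"] = defined
    return out
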