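"""Per-subject sensory eye-dominance statistics.

The eye whose percept survives longer dominates: dominance is assigned by the
larger pooled median phase duration, and quantified by the eye dominance index

    EDI = 100 * (d_DE - d_NDE) / d_NDE   [percent],

the percentage increase of the dominant-eye median phase duration d_DE over the
non-dominant-eye median d_NDE.  Two auxiliary quantities are computed from the
time accounting: the perceptual suppression ratio
dominant_time / (dominant_time + mixed_time), and the mixed-percept fraction of
reported time used to screen out participants who spent most of the task in a
piecemeal percept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import rivalry
from .exceptions import (
    AmbiguousDominanceError,
    EmptySampleError,
    ParameterError,
)


@dataclass(frozen=True)
class EyeDominanceResult:
    """Eye-dominance summary for one subject."""

    subject_id: str
    d_de: float  # median dominant-eye phase duration, s
    d_nde: float
    dominant_eye: str  # "left" | "right"
    edi_pct: float
    suppression: float  # in (0, 1]
    mixed_fraction_pct: float  # percent of reported time in mixed percept
    n_phases_de: int
    n_phases_nde: int


def median_duration(sample) -> float:
    """Sample median (midpoint of the two central order statistics for even n).

    Raises :class:`EmptySampleError` on an empty sample — the upstream pooling
    flags eyes with no surviving phases and the median must not be computed.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise EmptySampleError("cannot take the median of an empty duration sample")
    return float(np.median(arr))


def assign_dominance(median_left: float, median_right: float) -> str:
    """Eye with the strictly larger median phase duration.

    An exact tie raises :class:`AmbiguousDominanceError`; there is no silent
    tie-break, the caller must decide explicitly.
    """
    if not (median_left > 0 and median_right > 0):
        raise ParameterError("median phase durations must be positive")
    if median_left == median_right:
        raise AmbiguousDominanceError(
            f"median phase durations tie exactly at {median_left}; "
            "pass tie_break to choose a dominant eye explicitly"
        )
    return "left" if median_left > median_right else "right"


def eye_dominance_index(d_de: float, d_nde: float) -> float:
    """EDI = 100 * (d_DE - d_NDE) / d_NDE, in percent; always >= 0 because the
    dominant eye is defined as the one with the larger median."""
    if not d_nde > 0:
        raise ParameterError(f"d_nde must be positive, got {d_nde}")
    if d_de < d_nde:
        raise ParameterError(
            f"d_de ({d_de}) < d_nde ({d_nde}): dominance mis-assigned upstream"
        )
    return 100.0 * (d_de - d_nde) / d_nde


def perceptual_suppression(dominant_time: float, mixed_time: float) -> float:
    """Proportion of reported dominant-percept time relative to dominant plus
    mixed percept time; in (0, 1]."""
    if not dominant_time > 0:
        raise ParameterError(f"dominant_time must be positive, got {dominant_time}")
    if mixed_time < 0:
        raise ParameterError(f"mixed_time must be >= 0, got {mixed_time}")
    return dominant_time / (dominant_time + mixed_time)


def screen_mixed_fraction(
    mixed_time: float, reported_time: float, threshold_pct: float
) -> bool:
    """Participant inclusion flag: True (include) unless the mixed percept
    accounts for at least ``threshold_pct`` percent of reported time."""
    if not 0 < threshold_pct < 100:
        raise ParameterError(
            f"threshold_pct must be in (0, 100), got {threshold_pct}"
        )
    if not reported_time > 0:
        raise ParameterError("reported_time must be positive")
    if not 0 <= mixed_time <= reported_time:
        raise ParameterError("mixed_time must lie in [0, reported_time]")
    return 100.0 * mixed_time / reported_time < threshold_pct


def compute_eye_dominance(
    subject_id: str,
    preprocessed_runs: Iterable,
    include_censored: bool = False,
    tie_break: str | None = None,
) -> EyeDominanceResult:
    """Full per-subject eye-dominance summary from preprocessed runs.

    Medians are computed on duration samples pooled across the subject's runs
    (censored phases excluded from the samples by default).  Time-based
    quantities (suppression, mixed fraction) use all surviving eye-phase time
    including censored phases, since they are proportions of reported time
    rather than duration statistics.
    """
    pps = list(preprocessed_runs)
    pooled = rivalry.pool_durations(pps, include_censored=include_censored)
    med_left = median_duration(pooled.sample("left"))
    med_right = median_duration(pooled.sample("right"))
    try:
        dominant = assign_dominance(med_left, med_right)
    except AmbiguousDominanceError:
        if tie_break not in ("left", "right"):
            raise
        dominant = tie_break
    d_de, d_nde = (
        (med_left, med_right) if dominant == "left" else (med_right, med_left)
    )
    edi = eye_dominance_index(d_de, d_nde)

    dom_label = rivalry.LEFT_EYE if dominant == "left" else rivalry.RIGHT_EYE
    dominant_time = sum(
        ph.duration for pp in pps for ph in pp.phases if ph.label == dom_label
    )
    kept_time = sum(pp.accounting.kept_eye_time for pp in pps)
    mixed_time = sum(pp.accounting.mixed_time for pp in pps)
    suppression = perceptual_suppression(dominant_time, mixed_time)
    reported = kept_time + mixed_time
    mixed_fraction_pct = 100.0 * mixed_time / reported if reported > 0 else 0.0

    n_de = pooled.sample(dominant).size
    n_nde = pooled.sample("left" if dominant == "right" else "right").size
    return EyeDominanceResult(
        subject_id=subject_id,
        d_de=d_de,
        d_nde=d_nde,
        dominant_eye=dominant,
        edi_pct=edi,
        suppression=suppression,
        mixed_fraction_pct=mixed_fraction_pct,
        n_phases_de=int(n_de),
        n_phases_nde=int(n_nde),
    )


def dominance_table(results: Iterable[EyeDominanceResult]) -> pd.DataFrame:
    """One row per subject with all :class:`EyeDominanceResult` fields."""
    rows = [
        {
            "subject": r.subject_id,
            "d_de": r.d_de,
            "d_nde": r.d_nde,
            "dominant_eye": r.dominant_eye,
            "edi_pct": r.edi_pct,
            "suppression": r.suppression,
            "mixed_fraction_pct": r.mixed_fraction_pct,
            "n_phases_de": r.n_phases_de,
            "n_phases_nde": r.n_phases_nde,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
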