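"""Synthetic rivalry streams and metabolite tables with known ground truth.

Every pipeline stage can be verified against simulated data because the
generator emits both the degraded observables (keypress streams with motor
latency, dropout and mixed-percept interludes; metabolite tables with CRLB
noise) and the clean ground truth they were produced from.

Phase durations are gamma distributed per eye — the standard family for the
right-skewed dominance phases of bistable perception — with the dominant eye
given a proportionally larger scale, so the true EDI follows from the scale
ratio (the gamma median is linear in the scale at fixed shape).  Mixed
interludes are inserted at transitions, not as standalone percept competitors;
dropout converts a phase's report to ``none``, exercising the missing-data
rule.  Metabolite noise is additive Gaussian on the simulated water-scaled
value, truncated at zero; CRLBs are drawn independently — no spectral-fitting
physics is modelled.

Cohort-level coupling between the true EDI and the true interocular GABA is
imposed through a Gaussian copula on the latent scale, so ``latent_effect``
is a target Spearman rank correlation between the two traits.

Default parameter choices (study conditions and calibration rationale) are
documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dominance import compute_eye_dominance
from .exceptions import EyeGabaError, ParameterError
from .mrs import GroupTissueMeans
from .rivalry import (
    LEFT_EYE,
    MIXED,
    RIGHT_EYE,
    KeypressEvent,
    PerceptPhase,
    RivalryRun,
    preprocess_run,
)

__all__ = [
    "RivalrySimParams",
    "CohortSimParams",
    "CohortGroundTruth",
    "CohortData",
    "simulate_rivalry_run",
    "true_edi",
    "gamma_median",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class RivalrySimParams:
    """Per-subject rivalry generator parameters (durations in seconds)."""

    gamma_shape_de: float = 6.0
    gamma_scale_de: float = 0.30483  # ~1.728 s median -> EDI 8% vs NDE
    gamma_shape_nde: float = 6.0
    gamma_scale_nde: float = 0.28225  # ~1.6 s median
    p_mixed: float = 0.15  # probability a transition passes through a mixed interlude
    mixed_mean: float = 0.6
    latency_mean: float = 0.2  # report delay, exponential
    p_dropout: float = 0.03  # probability a phase is reported as "none"
    run_duration: float = 180.0
    n_runs: int = 3
    dominant_eye: str = "right"
    seed: int | None = None

    def __post_init__(self):
        for name in ("gamma_shape_de", "gamma_scale_de", "gamma_shape_nde",
                     "gamma_scale_nde", "mixed_mean", "run_duration"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("p_mixed", "p_dropout"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.latency_mean < 0:
            raise ParameterError("latency_mean must be >= 0")
        if self.dominant_eye not in ("left", "right"):
            raise ParameterError("dominant_eye must be 'left' or 'right'")


def gamma_median(shape: float, scale: float) -> float:
    """Median of a gamma distribution by root-finding on its CDF."""
    hi = shape * scale * 20.0 + 10.0
    return float(
        optimize.brentq(
            lambda x: stats.gamma.cdf(x, a=shape, scale=scale) - 0.5,
            1e-12,
            hi,
            xtol=1e-12,
        )
    )


def true_edi(params: RivalrySimParams) -> float:
    """EDI (percent) implied by the generating distributions' medians."""
    d_de = gamma_median(params.gamma_shape_de, params.gamma_scale_de)
    d_nde = gamma_median(params.gamma_shape_nde, params.gamma_scale_nde)
    return 100.0 * (d_de - d_nde) / d_nde


def _state_for_label(label: str, cw_eye: str) -> str:
    if label == MIXED:
        return "mixed"
    eye = "left" if label == LEFT_EYE else "right"
    return "cw" if eye == cw_eye else "ccw"


def simulate_rivalry_run(
    params: RivalrySimParams,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    run_id: str | int = 1,
):
    """One rivalry run: returns ``(RivalryRun, ground-truth phases)``.

    The ground-truth phases partition ``[0, run_duration]`` exactly; the
    keypress stream is the degraded report of them (latency-delayed, thinned by
    dropout).  Fully reproducible from the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    de, nde = params.dominant_eye, ("left" if params.dominant_eye == "right" else "right")
    shape = {de: params.gamma_shape_de, nde: params.gamma_shape_nde}
    scale = {de: params.gamma_scale_de, nde: params.gamma_scale_nde}
    label = {"left": LEFT_EYE, "right": RIGHT_EYE}

    truth: list[PerceptPhase] = []
    t = 0.0
    eye = "left" if rng.random() < 0.5 else "right"
    while t < params.run_duration:
        dur = rng.gamma(shape[eye], scale[eye])
        truth.append(PerceptPhase(t, t + dur, label[eye]))
        t += dur
        if t >= params.run_duration:
            break
        if params.p_mixed > 0 and rng.random() < params.p_mixed:
            mdur = rng.exponential(params.mixed_mean)
            truth.append(PerceptPhase(t, t + mdur, MIXED))
            t += mdur
        eye = "left" if eye == "right" else "right"
    last = truth[-1]
    truth[-1] = PerceptPhase(
        last.onset, params.run_duration, last.label, censored=True
    )

    cw_eye = "left" if rng.random() < 0.5 else "right"
    events: list[KeypressEvent] = []
    for ph in truth:
        delay = rng.exponential(params.latency_mean) if params.latency_mean > 0 else 0.0
        t_ev = ph.onset + delay
        dropped = params.p_dropout > 0 and rng.random() < params.p_dropout
        state = "none" if dropped else _state_for_label(ph.label, cw_eye)
        if t_ev >= params.run_duration:
            continue
        if events and t_ev <= events[-1].time:
            continue  # report overtaken by the next phase's report
        events.append(KeypressEvent(t_ev, state))
    run = RivalryRun(
        tuple(events), params.run_duration, cw_eye, subject_id=subject_id, run_id=run_id
    )
    return run, truth


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort generator: study-sized design with a controllable latent
    coupling between true EDI and true interocular GABA."""

    n_subjects: int = 12
    latent_effect: float = 0.0  # target Spearman rho between the two traits
    # trait distributions
    edi_mean: float = 7.9  # percent
    edi_sd: float = 8.2
    interocular_mean: float = 0.03
    interocular_sd: float = 0.05
    gaba_mean: float = 0.91  # between-subject GABA:H2O-scale level
    gaba_between_sd: float = 0.10
    tcr_mean: float = 1.12
    tcr_sd: float = 0.08
    # measurement model
    gaba_noise_sd: float = 0.01  # additive, on the water-scaled value
    crlb_mean: float = 28.1  # percent, GABA
    crlb_sd: float = 3.7
    tcr_crlb_mean: float = 3.0
    tcr_crlb_sd: float = 0.5
    block_effect: float = 0.05  # fractional checkerboard > fixation GABA increase
    bold_mean: float = 2.0  # %BOLD change, per eye, no built-in eye effect
    bold_sd: float = 0.5
    # voxel composition
    tissue_means: tuple = (0.438, 0.50, 0.062)  # GM, WM, CSF
    tissue_sds: tuple = (0.029, 0.039, 0.023)
    alpha: float = 0.5
    rivalry: RivalrySimParams = field(default_factory=RivalrySimParams)
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ParameterError("n_subjects must be >= 3")
        if abs(self.latent_effect) >= 1:
            raise ParameterError("|latent_effect| must be < 1")
        for name in ("edi_sd", "interocular_sd", "gaba_between_sd",
                     "gaba_noise_sd", "crlb_sd", "bold_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class CohortGroundTruth:
    """Per-subject true quantities plus the realised (pre-degradation) phases."""

    subjects: pd.DataFrame
    run_phases: dict
    mu: GroupTissueMeans
    params: CohortSimParams


@dataclass
class CohortData:
    """Everything the pipeline consumes, plus the ground truth."""

    runs_by_subject: dict
    metab: pd.DataFrame
    tissue: pd.DataFrame
    bold: pd.DataFrame
    truth: CohortGroundTruth


def _truncated_normal(rng, mean, sd, size, lower=1e-3):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lower, None)


def simulate_cohort(params: CohortSimParams) -> CohortData:
    """Draw a full cohort: rivalry keypress streams, metabolite and tissue
    tables, per-eye %BOLD values, and the generating ground truth.

    The water-scaled metabolite values are constructed by inverting the CSF and
    alpha corrections at the cohort's own group tissue means, so with zero
    noise the corrected pipeline output equals the simulated tissue-level
    concentration exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    subjects = [f"S{i + 1:02d}" for i in range(n)]

    # latent traits through a Gaussian copula
    rho = 2.0 * np.sin(np.pi * params.latent_effect / 6.0)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    k = (params.edi_mean / params.edi_sd) ** 2
    theta = params.edi_sd**2 / params.edi_mean
    edi_true = stats.gamma.ppf(stats.norm.cdf(z1), a=k, scale=theta)
    edi_true = np.clip(edi_true, 1e-3, None)
    inter_true = params.interocular_mean + params.interocular_sd * z2
    inter_true = np.clip(inter_true, -0.9, None)

    dominant = np.where(rng.random(n) < 0.5, "left", "right")

    # voxel composition, renormalised to a unit simplex
    comp = np.column_stack(
        [
            _truncated_normal(rng, m, s, n, lower=0.01)
            for m, s in zip(params.tissue_means, params.tissue_sds)
        ]
    )
    comp /= comp.sum(axis=1, keepdims=True)
    tissue = pd.DataFrame(
        {"subject": subjects, "f_gm": comp[:, 0], "f_wm": comp[:, 1], "f_csf": comp[:, 2]}
    )
    mu = GroupTissueMeans(float(comp[:, 0].mean()), float(comp[:, 1].mean()))

    # rivalry runs
    runs_by_subject: dict[str, list[RivalryRun]] = {}
    run_phases: dict[str, list] = {}
    base = params.rivalry
    d_nde_true = gamma_median(base.gamma_shape_nde, base.gamma_scale_nde)
    for i, sid in enumerate(subjects):
        scale_de = base.gamma_scale_nde * (1.0 + edi_true[i] / 100.0)
        p = replace(
            base,
            gamma_shape_de=base.gamma_shape_nde,
            gamma_scale_de=scale_de,
            dominant_eye=str(dominant[i]),
        )
        runs, phases = [], []
        for r in range(base.n_runs):
            run, truth = simulate_rivalry_run(p, rng, subject_id=sid, run_id=r + 1)
            runs.append(run)
            phases.append(truth)
        runs_by_subject[sid] = runs
        run_phases[sid] = phases

    # The scanner's DE/NDE condition labels reproduce the study's procedure:
    # dominance is assigned from the behavioural (rivalry) session that precedes
    # scanning, i.e. from the simulated keypress streams, not from the latent
    # truth.  With no degradation the two coincide.
    assigned = []
    for i, sid in enumerate(subjects):
        try:
            pps = [preprocess_run(r) for r in runs_by_subject[sid]]
            res = compute_eye_dominance(sid, pps, tie_break="right")
            assigned.append(res.dominant_eye)
        except EyeGabaError:
            assigned.append(str(dominant[i]))
    assigned = np.asarray(assigned)

    # metabolite levels (tissue scale); interocular truth is defined relative
    # to the true dominant eye
    gaba_nde = _truncated_normal(rng, params.gaba_mean, params.gaba_between_sd, n, 0.2)
    gaba_de = gaba_nde * (1.0 + inter_true)
    gaba_rest = _truncated_normal(rng, params.gaba_mean, params.gaba_between_sd, n, 0.2)
    tcr = _truncated_normal(rng, params.tcr_mean, params.tcr_sd, n, 0.3)
    # per-eye levels, then condition labels via the behavioural assignment
    gaba_eye = {
        "left": np.where(dominant == "left", gaba_de, gaba_nde),
        "right": np.where(dominant == "right", gaba_de, gaba_nde),
    }
    gaba_cond_de = np.array([gaba_eye[assigned[i]][i] for i in range(n)])
    gaba_cond_nde = np.array(
        [gaba_eye["left" if assigned[i] == "right" else "right"][i] for i in range(n)]
    )

    # invert the corrections so the pipeline recovers tissue-level truth
    a = params.alpha
    inv = (
        (1.0 - comp[:, 2])
        * (comp[:, 0] + a * comp[:, 1])
        * (mu.mu_gm + mu.mu_wm)
        / (mu.mu_gm + a * mu.mu_wm)
    )

    rows = []
    for i, sid in enumerate(subjects):
        level = {"DE": gaba_cond_de[i], "NDE": gaba_cond_nde[i], "rest": gaba_rest[i]}
        for cond in ("DE", "NDE", "rest"):
            blocks = ("all",) if cond == "rest" else ("all", "checkerboard", "fixation")
            for block in blocks:
                g = level[cond]
                if block == "checkerboard":
                    g = g * (1.0 + params.block_effect)
                for met, true_level, cm, cs in (
                    ("GABA", g, params.crlb_mean, params.crlb_sd),
                    ("tCr", tcr[i], params.tcr_crlb_mean, params.tcr_crlb_sd),
                ):
                    raw = true_level * inv[i]
                    if params.gaba_noise_sd > 0:
                        raw = max(raw + rng.normal(0.0, params.gaba_noise_sd), 1e-6)
                    rows.append(
                        {
                            "subject": sid,
                            "condition": cond,
                            "block": block,
                            "metabolite": met,
                            "value": raw,
                            "crlb_pct": max(rng.normal(cm, cs), 0.0),
                            "reference": "water",
                        }
                    )
    metab = pd.DataFrame(rows)

    bold = pd.DataFrame(
        {
            "subject": np.repeat(subjects, 2),
            "condition": ["DE", "NDE"] * n,
            "pbold_change": rng.normal(params.bold_mean, params.bold_sd, 2 * n),
        }
    )

    truth_df = pd.DataFrame(
        {
            "subject": subjects,
            "true_edi_pct": edi_true,
            "true_d_de": d_nde_true * (1.0 + edi_true / 100.0),
            "true_d_nde": d_nde_true,
            "dominant_eye": dominant,
            "assigned_eye": assigned,
            "true_interocular": inter_true,
            # interocular truth under the behavioural DE/NDE assignment the
            # scanner conditions actually used (flips when the assignment
            # disagrees with the latent dominant eye)
            "true_interocular_assigned": np.where(
                assigned == dominant, inter_true, -inter_true / (1.0 + inter_true)
            ),
            "gaba_de": gaba_de,
            "gaba_nde": gaba_nde,
            "gaba_rest": gaba_rest,
            "tcr": tcr,
            "f_gm": comp[:, 0],
            "f_wm": comp[:, 1],
            "f_csf": comp[:, 2],
        }
    )
    truth = CohortGroundTruth(truth_df, run_phases, mu, params)
    return CohortData(runs_by_subject, metab, tissue, bold, truth)


def write_cohort(data: CohortData, outdir) -> None:
    """Write the pipeline input files (keypress CSVs + run configs, metabolite,
    tissue and BOLD tables) in the dialects the other modules consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, runs in data.runs_by_subject.items():
        for run in runs:
            stem = f"{sid}_run{run.run_id}"
            with open(out / f"{stem}.csv", "w") as fh:
                fh.write("time_s,state\n")
                for ev in run.events:
                    fh.write(f"{ev.time:.6f},{ev.state}\n")
            with open(out / f"{stem}.cfg", "w") as fh:
                fh.write(f"subject = {sid}\n")
                fh.write(f"run = {run.run_id}\n")
                fh.write(f"duration_s = {run.duration}\n")
                fh.write(f"cw_eye = {run.cw_eye}\n")
    data.metab.to_csv(out / "metabolites.csv", index=False)
    data.tissue.to_csv(out / "tissue.csv", index=False)
    data.bold.to_csv(out / "bold.csv", index=False)
    data.truth.subjects.to_csv(out / "ground_truth.csv", index=False)
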