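"""Readers and writers for the package's plain-text dialects.

Keypress log CSV (one per run): header ``time_s,state`` with states
``cw|ccw|mixed|none``.  Sidecar run metadata is a plain ``key = value`` file
with keys subject, run, duration_s, cw_eye.  Tables (metabolite, tissue,
dominance, levels, report) are ordinary CSVs handled by pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import MalformedInputError
from .rivalry import KeypressEvent, PerceptPhase, RivalryRun


def read_kv_config(path) -> dict:
    """Parse a plain ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise MalformedInputError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_keypress_csv(path) -> list:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "state"]:
        raise MalformedInputError(
            f"{path}: expected header 'time_s,state', got {list(df.columns)}"
        )
    return [KeypressEvent(float(t), str(s)) for t, s in zip(df["time_s"], df["state"])]


def load_run(csv_path, cfg_path) -> RivalryRun:
    """Keypress CSV + sidecar metadata -> :class:`RivalryRun`."""
    cfg = read_kv_config(cfg_path)
    try:
        return RivalryRun(
            events=tuple(read_keypress_csv(csv_path)),
            duration=float(cfg["duration_s"]),
            cw_eye=cfg["cw_eye"],
            subject_id=cfg.get("subject", "unknown"),
            run_id=cfg.get("run", 0),
        )
    except KeyError as exc:
        raise MalformedInputError(f"{cfg_path}: missing key {exc}") from exc


def load_run_directory(directory) -> dict:
    """All ``*.csv`` + matching ``*.cfg`` pairs in a directory, grouped by
    subject."""
    runs: dict[str, list[RivalryRun]] = {}
    for csv_path in sorted(Path(directory).glob("*.csv")):
        cfg_path = csv_path.with_suffix(".cfg")
        if not cfg_path.exists():
            continue
        run = load_run(csv_path, cfg_path)
        runs.setdefault(run.subject_id, []).append(run)
    return runs


def phases_frame(phases) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [p.onset for p in phases],
            "offset_s": [p.offset for p in phases],
            "label": [p.label for p in phases],
            "censored": [p.censored for p in phases],
        }
    )


def write_phases_csv(phases, path) -> None:
    phases_frame(phases).to_csv(path, index=False)


def read_phases_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        PerceptPhase(float(r.onset_s), float(r.offset_s), str(r.label), bool(r.censored))
        for r in df.itertuples()
    ]
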