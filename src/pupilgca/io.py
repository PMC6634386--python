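"""Reading and writing the pipeline's file formats.

Sample streams travel as EyeLink-style tab-separated sample reports
(one row per sample: session label, trial index, absolute timestamp,
pupil size in tracker units, blink flag, plus trial variables); trial
metadata and binned trials as tidy CSV; fitted models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lmm import LmmFit
from .simulate import RawPupilSeries

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "write_sample_report",
    "read_sample_report",
    "write_trial_metadata",
    "read_trial_metadata",
    "fit_to_dict",
    "write_fit_json",
]

DEFAULT_COLUMN_MAP = {
    "participant": "RECORDING_SESSION_LABEL",
    "trial": "TRIAL_INDEX",
    "timestamp": "TIMESTAMP",
    "pupil": "PUPIL_SIZE",
    "blink": "IN_BLINK",
    "condition": "CONDITION",
    "item": "ITEM_ID",
}

_TRIAL_SPACING_MS = 100_000.0  # absolute-clock spacing between trial starts


def write_sample_report(
    series: list[RawPupilSeries],
    path,
    au_scale: float = 1000.0,
    column_map: dict | None = None,
) -> Path:
    """Write trials as a tab-separated EyeLink-style sample report.

    Pupil values are emitted in arbitrary units (``mm * au_scale``);
    missing samples are written as 0 with the blink flag set, the way
    tracker exports encode blinks.  Timestamps are an absolute per-trial
    clock; word-pair onset is recoverable because the fixation epoch has
    negative trial-relative time.
    """
    cm = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    frames = []
    for s in series:
        if s.unit != "mm":
            raise ValueError("write_sample_report expects series in mm")
        pupil_au = np.where(s.valid, s.pupil * au_scale, 0.0)
        t0 = _TRIAL_SPACING_MS * s.trial_id
        frames.append(
            pd.DataFrame(
                {
                    cm["participant"]: f"p{s.participant_id:03d}",
                    cm["trial"]: s.trial_id,
                    cm["timestamp"]: t0 + (s.time_ms - s.time_ms[0]),
                    cm["pupil"]: pupil_au,
                    cm["blink"]: (~s.valid).astype(int),
                    cm["condition"]: s.condition,
                    cm["item"]: s.item_id,
                    "FIXATION_MS": -s.time_ms[0],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_sample_report(
    path,
    column_map: dict | None = None,
    fixation_ms: float | None = None,
) -> list[RawPupilSeries]:
    """Parse a sample report into one series per participant x trial.

    Timestamps are re-referenced to word-pair onset: onset is the trial's
    first timestamp plus the fixation duration (taken from a FIXATION_MS
    column when present, else the ``fixation_ms`` argument, default
    1000).  Zero or absent pupil readings and set blink flags become
    invalid samples.

    Raises
    ------
    ValueError
        If mapped columns are missing (named in the message) or
        timestamps within a trial are not strictly increasing.
    """
    cm = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep="\t")
    required = [cm["participant"], cm["trial"], cm["timestamp"], cm["pupil"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample report missing columns: {missing}")
    out = []
    for (part, trial), g in df.groupby([cm["participant"], cm["trial"]], sort=True):
        ts = g[cm["timestamp"]].to_numpy(float)
        if np.any(np.diff(ts) <= 0):
            raise ValueError(
                f"non-monotone timestamps in trial {trial} of {part}"
            )
        fix = (
            float(g["FIXATION_MS"].iloc[0])
            if "FIXATION_MS" in g.columns
            else (1000.0 if fixation_ms is None else fixation_ms)
        )
        pupil = g[cm["pupil"]].to_numpy(float)
        blink = (
            g[cm["blink"]].to_numpy(int).astype(bool)
            if cm["blink"] in g.columns
            else np.zeros(len(g), bool)
        )
        valid = ~blink & (pupil > 0) & ~np.isnan(pupil)
        pupil = np.where(valid, pupil, np.nan)
        pid = int(str(part).lstrip("p")) if str(part).lstrip("p").isdigit() else part
        out.append(
            RawPupilSeries(
                participant_id=pid,
                trial_id=int(trial),
                item_id=int(g[cm["item"]].iloc[0]) if cm["item"] in g.columns else -1,
                condition=str(g[cm["condition"]].iloc[0]) if cm["condition"] in g.columns else "unknown",
                time_ms=ts - ts[0] - fix,
                pupil=pupil,
                valid=valid,
                unit="au",
            )
        )
    return out


def write_trial_metadata(behavior: pd.DataFrame, path) -> Path:
    path = Path(path)
    behavior.to_csv(path, index=False)
    return path


def read_trial_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "item", "sem_type", "strength", "rt_ms", "accuracy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial metadata missing columns: {sorted(missing)}")
    return df


def fit_to_dict(fit: LmmFit) -> dict:
    return {
        "coefficients": fit.params.reset_index(names="term").to_dict(orient="records"),
        "varcomps": fit.varcomps,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
        "n_params": fit.n_params,
        "converged": fit.converged,
        "method": fit.method,
        "structure": fit.structure,
        "notes": list(fit.notes),
    }


def write_fit_json(fit: LmmFit, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=2, default=float)
    return path
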