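"""Readers and writers for visit logs, curves and fit results.

The shared log schema is a CSV with one row per well visit:
``subject_id, session, visit_index, arm, reward`` plus optional
``trial_type``/``is_error`` columns. Trial types and error labels are
always recomputed from the task rules on read; if the file carries its own
labels they are cross-checked and any disagreement is reported (the
recomputed values win). Curves are written as tidy CSV
(``visit, value, sem, kind``), fit results as JSON.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import task
from .cohort import scripted_log

REQUIRED_COLUMNS = ("subject_id", "session", "visit_index", "arm", "reward")


class LogSchemaError(ValueError):
    """A visit-log file violates the shared schema."""


def _validate_subject(df: pd.DataFrame, subject: str) -> pd.DataFrame:
    arms = df["arm"].to_numpy()
    bad = ~np.isin(arms, task.ARMS)
    if bad.any():
        row = df.index[bad][0]
        raise LogSchemaError(
            f"subject {subject}: invalid arm {df.loc[row, 'arm']} at row {row}"
        )
    rew = df["reward"].to_numpy()
    if not np.isin(rew, (0, 1)).all():
        row = df.index[~np.isin(rew, (0, 1))][0]
        raise LogSchemaError(
            f"subject {subject}: invalid reward {df.loc[row, 'reward']} at row {row}"
        )
    vi = df["visit_index"].to_numpy()
    if not (np.diff(vi) > 0).all():
        row = df.index[1:][np.diff(vi) <= 0][0]
        raise LogSchemaError(
            f"subject {subject}: visit_index not strictly increasing at row {row}"
        )
    ses = df["session"].to_numpy()
    if not (np.diff(ses) >= 0).all():
        row = df.index[1:][np.diff(ses) < 0][0]
        raise LogSchemaError(
            f"subject {subject}: session numbers decrease at row {row}"
        )
    # collapse accidental immediate repeats within a session
    same = np.zeros(len(df), dtype=bool)
    same[1:] = (np.diff(arms) == 0) & (np.diff(ses) == 0)
    if same.any():
        warnings.warn(
            f"subject {subject}: collapsed {int(same.sum())} immediate repeat "
            "visit(s) — the task forbids revisiting the current arm"
        )
        df = df.loc[~same]
    return df


def _recompute_labels(df: pd.DataFrame, subject: str) -> pd.DataFrame:
    lengths = df.groupby("session", sort=True).size().to_list()
    fresh = scripted_log(df["arm"].to_list(), lengths)
    for col in ("trial_type", "is_error"):
        if col in df.columns:
            mismatch = (
                df[col].to_numpy() != fresh[col].to_numpy()
            )
            if mismatch.any():
                warnings.warn(
                    f"subject {subject}: {int(mismatch.sum())} {col} value(s) "
                    "disagree with the task rules; recomputed values used"
                )
    out = df[list(REQUIRED_COLUMNS)].reset_index(drop=True).copy()
    out["reward"] = fresh["reward"]  # rewards implied by the rules
    out["trial_type"] = fresh["trial_type"]
    out["is_error"] = fresh["is_error"]
    out["session_start"] = fresh["session_start"]
    return out


def read_log(path, recompute_rewards: bool = False) -> list[pd.DataFrame]:
    """Read and validate a visit-log CSV; one DataFrame per subject.

    Labels derivable from the task rules (trial type, error flag, session
    starts) are recomputed; stored labels, when present, are cross-checked
    with a warning on disagreement. Stored rewards are kept verbatim unless
    ``recompute_rewards`` is set (real logs may contain hardware
    idiosyncrasies the rules do not model).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LogSchemaError(f"{path}: missing required column(s) {missing}")
    logs = []
    for subject, sub in df.groupby("subject_id", sort=True):
        sub = _validate_subject(sub.reset_index(drop=True), str(subject))
        stored_reward = sub["reward"].to_numpy()
        out = _recompute_labels(sub, str(subject))
        if not recompute_rewards:
            if (out["reward"].to_numpy() != stored_reward).any():
                n = int((out["reward"].to_numpy() != stored_reward).sum())
                warnings.warn(
                    f"subject {subject}: {n} stored reward(s) disagree with "
                    "the delivery rule; stored values kept"
                )
            out["reward"] = stored_reward
        logs.append(out)
    return logs


def write_log(logs, path) -> None:
    """Write a collection of per-subject logs as one CSV."""
    frames = []
    for i, log in enumerate(logs):
        log = log.copy()
        if "subject_id" not in log.columns:
            log.insert(0, "subject_id", f"subj{i:02d}")
        frames.append(log)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_curves(curves, path) -> None:
    """Write BehaviorCurves as tidy CSV (visit, value, sem, kind)."""
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, index=False
    )


def read_curves(path) -> pd.DataFrame:
    return pd.read_csv(path)
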