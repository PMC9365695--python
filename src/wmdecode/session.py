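"""Trial-log data model: schema, TSV I/O, trial filtering and experiment partitioning.

A session is a continuous sequence of trials, each composed of a grey-screen
delay followed by a grating stimulus.  The stimulus of each trial serves as the
cue to the next trial, so the delay of trial *i* is labelled by the stimulus of
trial *i - 1* (``prev_cue_identity``).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TASKS = ("DISC", "WM")
ROTATIONS = ("CW", "CCW", "NONE")
TRIAL_TYPES = ("cue", "probe", "target")
CUE_IDS = ("A", "B", "NA")
OUTCOMES = ("hit", "miss", "FA", "CR", "NA")
OPTO_EPOCHS = ("none", "delay_onset", "delay_end", "stim_onset")

#: mandatory columns of a trial table, with the set of allowed values for
#: categorical columns (None = numeric/boolean/free text).
TRIAL_SCHEMA: dict[str, tuple | None] = {
    "trial_index": None,
    "task": TASKS,
    "rotation": ROTATIONS,
    "trial_type": TRIAL_TYPES,
    "cue_identity": CUE_IDS,
    "prev_cue_identity": CUE_IDS,
    "stimulus_orientation": None,
    "delay_ms": None,
    "stimulus_ms": None,
    "delay_onset_ms": None,
    "lick_latency_ms": None,
    "outcome": OUTCOMES,
    "opto_epoch": OPTO_EPOCHS,
    "opto_area": None,
    "halted": None,
    "early_lick": None,
}

_BOOL_COLS = ("halted", "early_lick")
_FLOAT_COLS = (
    "stimulus_orientation",
    "delay_ms",
    "stimulus_ms",
    "delay_onset_ms",
    "lick_latency_ms",
)


class SchemaError(ValueError):
    """A trial table is missing a mandatory column or holds an invalid value."""


class NoTrialsError(ValueError):
    """All trials were removed by the requested filters."""


@dataclass
class SessionTable:
    """One behavioural session: an ordered trial table plus recording metadata."""

    trials: pd.DataFrame
    mouse_id: str = "m0"
    area: str = "AM"
    frame_rate_hz: float = 4.68

    def __post_init__(self) -> None:
        validate_trials(self.trials)
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        idx = self.trials["trial_index"].to_numpy()
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise SchemaError("trial_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def with_trials(self, trials: pd.DataFrame) -> "SessionTable":
        return replace(self, trials=trials.reset_index(drop=True))


def validate_trials(df: pd.DataFrame) -> None:
    for col, allowed in TRIAL_SCHEMA.items():
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
        if allowed is not None:
            bad = ~df[col].isin(allowed)
            if bad.any():
                i = int(df.loc[bad, "trial_index"].iloc[0])
                val = df.loc[bad, col].iloc[0]
                raise SchemaError(
                    f"invalid value {val!r} in column {col} at trial_index {i}"
                )


def read_session_table(path) -> SessionTable:
    """Read a session TSV.  Lines starting with ``#`` carry session metadata."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    # keep_default_na=False: "NA" is a legitimate enum value, not missing data
    df = pd.read_csv(
        io.StringIO("\n".join(body_lines)), sep="\t", keep_default_na=False,
        float_precision="round_trip",
    )
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False}
            )
    for col in _FLOAT_COLS:
        if col in df.columns:
            if df[col].dtype == object:
                # empty strings mark absent values; float() parsing is
                # correctly rounded, unlike the fast to_numeric path
                df[col] = df[col].replace("", np.nan).map(
                    lambda v: v if isinstance(v, float) else float(v)
                )
            df[col] = pd.to_numeric(df[col])
    if "opto_area" in df.columns:
        df["opto_area"] = df["opto_area"].fillna("NA").astype(str)
    return SessionTable(
        trials=df,
        mouse_id=meta.get("mouse_id", "m0"),
        area=meta.get("area", "AM"),
        frame_rate_hz=float(meta.get("frame_rate_hz", 4.68)),
    )


def write_session_table(session: SessionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mouse_id = {session.mouse_id}\n")
        fh.write(f"# area = {session.area}\n")
        fh.write(f"# frame_rate_hz = {session.frame_rate_hz}\n")
        session.trials.to_csv(fh, sep="\t", index=False)


def _follows_probe_or_target(df: pd.DataFrame) -> np.ndarray:
    """True for trials whose immediate predecessor (trial_index - 1) in *df* is a
    probe or a target.  Predecessors absent from the table cannot trigger removal,
    which makes the filter idempotent."""
    idx = df["trial_index"].to_numpy()
    ttype = df["trial_type"].to_numpy()
    pos_of = {int(i): p for p, i in enumerate(idx)}
    out = np.zeros(len(df), dtype=bool)
    for p, i in enumerate(idx):
        q = pos_of.get(int(i) - 1)
        if q is not None and ttype[q] in ("probe", "target"):
            out[p] = True
    return out


def filter_trials(session: SessionTable, cfg=None, imaging: bool = False) -> SessionTable:
    """Remove trials unusable for analysis.

    Drops halted trials, trials with a lick during the delay, trials immediately
    following a probe or target (the mandatory cues), and trials silenced at the
    end of the delay.  With ``imaging=True`` additionally drops trials whose delay
    exceeds the analysis cap (default 3.2 s).  Original trial indices survive in
    the ``trial_index`` column.
    """
    df = session.trials
    keep = (
        ~df["halted"].to_numpy()
        & ~df["early_lick"].to_numpy()
        & ~_follows_probe_or_target(df)
        & (df["opto_epoch"].to_numpy() != "delay_end")
    )
    if imaging:
        cap = cfg.analysis_delay_cap_ms if cfg is not None else 3200.0
        keep &= df["delay_ms"].to_numpy() <= cap
    out = df.loc[keep]
    if len(out) == 0:
        raise NoTrialsError("no trials survive filters")
    return session.with_trials(out)


@dataclass
class Experiment:
    """A pairing of Discrimination and WM blocks sharing a cue orientation."""

    name: str
    matched_orientation: float | None
    trial_index: np.ndarray  # original trial_index values included
    session: SessionTable = field(repr=False)

    def trials(self) -> pd.DataFrame:
        df = self.session.trials
        return df[df["trial_index"].isin(self.trial_index)]


def define_experiments(session: SessionTable) -> list[Experiment]:
    """Partition a session into up to two experiments.

    An experiment pairs Discrimination and WM blocks whose cue stimuli share a
    physical orientation across opposite rotation blocks (cue orientations are
    matched at -15 deg and +15 deg).  If only one shared orientation exists the
    experiment is the full session; with a single task, no contrast exists and
    the list is empty.
    """
    df = session.trials
    tasks = set(df["task"])
    if len(tasks & set(TASKS)) < 2:
        warnings.warn("session contains a single task; no experiments defined")
        return []
    rot_by_task = {t: set(df.loc[df["task"] == t, "rotation"]) for t in ("DISC", "WM")}
    # CW rotates all stimuli -15 deg, CCW +15 deg: the DISC cue (0 deg base) lands
    # on -15 in CW blocks and +15 in CCW blocks; the WM cues (+-30 base) produce a
    # -15 cue in CCW blocks and a +15 cue in CW blocks.
    pairings = [(-15.0, "CW", "CCW"), (15.0, "CCW", "CW")]
    experiments = []
    for ori, disc_rot, wm_rot in pairings:
        if disc_rot in rot_by_task["DISC"] and wm_rot in rot_by_task["WM"]:
            mask = ((df["task"] == "DISC") & (df["rotation"] == disc_rot)) | (
                (df["task"] == "WM") & (df["rotation"] == wm_rot)
            )
            if mask.any():
                experiments.append(
                    Experiment(
                        name=f"ori{ori:+.0f}",
                        matched_orientation=ori,
                        trial_index=df.loc[mask, "trial_index"].to_numpy(),
                        session=session,
                    )
                )
    if len(experiments) < 2:
        # fewer than two cross-rotation pairings: the whole session is the experiment
        return [
            Experiment(
                name="full_session",
                matched_orientation=None,
                trial_index=df["trial_index"].to_numpy(),
                session=session,
            )
        ]
    return experiments
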