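"""Deconvolved-activity containers, HDF5 I/O, and trial-frame alignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .session import SessionTable

SIGNAL_KINDS = ("soma", "bouton", "axon")


@dataclass
class ActivityStore:
    """Units x frames deconvolved activity with frame timestamps.

    ``activity`` holds deconvolved dF/F0 for somata, or baseline-subtracted dF
    for boutons/axons.  Columns correspond one-to-one with ``frame_times_ms``.
    """

    activity: np.ndarray
    frame_times_ms: np.ndarray
    unit_ids: list[str]
    signal_kind: str = "soma"
    frame_rate_hz: float = 4.68

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        if self.activity.ndim != 2:
            raise ValueError("activity must be units x frames")
        if self.activity.shape[1] != self.frame_times_ms.shape[0]:
            raise ValueError("activity columns must match frame_times_ms")
        if len(self.unit_ids) != self.activity.shape[0]:
            raise ValueError("unit_ids must match activity rows")
        if self.frame_times_ms.size > 1 and not np.all(np.diff(self.frame_times_ms) > 0):
            raise ValueError("frame_times_ms must be strictly increasing")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")

    @property
    def n_units(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("activity", data=self.activity.astype(np.float32))
            f.create_dataset("frame_times_ms", data=self.frame_times_ms)
            f.create_dataset(
                "unit_ids",
                data=np.array(self.unit_ids, dtype=h5py.string_dtype()),
            )
            f.attrs["signal_kind"] = self.signal_kind
            f.attrs["frame_rate_hz"] = self.frame_rate_hz

    @classmethod
    def from_hdf5(cls, path) -> "ActivityStore":
        with h5py.File(path, "r") as f:
            return cls(
                activity=f["activity"][()].astype(float),
                frame_times_ms=f["frame_times_ms"][()],
                unit_ids=[u.decode() if isinstance(u, bytes) else str(u) for u in f["unit_ids"][()]],
                signal_kind=str(f.attrs["signal_kind"]),
                frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            )


@dataclass
class TrialAlignedTensor:
    """Per-trial activity windows cut at a common alignment point.

    Windows are half-open ``[start, end)`` in milliseconds relative to the
    alignment event; a frame belongs to a window iff its temporal midpoint
    falls inside both the window and the trial's epoch.  Trials whose epoch or
    the recording end truncate the requested window are flagged ``incomplete``
    and never padded.
    """

    windows: list[np.ndarray]            # each units x n_frames_i
    trial_index: np.ndarray              # original trial_index per window
    incomplete: np.ndarray               # bool per window
    alignment: str
    window_ms: tuple[float, float]
    rel_times_ms: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_frames(self) -> np.ndarray:
        return np.array([w.shape[1] for w in self.windows], dtype=int)

    def trial_means(self, min_frames: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Per-trial mean over frames -> (trials x units, included mask)."""
        ok = self.n_frames >= min_frames
        n_units = self.windows[0].shape[0] if self.windows else 0
        out = np.full((len(self.windows), n_units), np.nan)
        for i, w in enumerate(self.windows):
            if ok[i]:
                out[i] = w.mean(axis=1)
        return out, ok


def align_trials(
    session: SessionTable,
    store: ActivityStore,
    alignment: str = "delay_onset",
    window_ms: tuple[float, float] = (0.0, 1600.0),
    restrict_to_epoch: bool = True,
) -> TrialAlignedTensor:
    """Cut per-trial frame windows at delay or stimulus onset.

    With ``restrict_to_epoch`` (the default) frames are never shared across the
    delay/stimulus boundary of a trial: delay-aligned windows only use frames
    inside the delay, stimulus-aligned windows only frames inside the stimulus.
    """
    if alignment not in ("delay_onset", "stim_onset"):
        raise ValueError("alignment must be 'delay_onset' or 'stim_onset'")
    start, end = window_ms
    if end < start:
        raise ValueError("window end must be >= start")
    mid = store.frame_times_ms + 0.5 * store.frame_period_ms
    rec_end = store.frame_times_ms[-1] + store.frame_period_ms if store.n_frames else 0.0

    windows, rel_times, incomplete, tidx = [], [], [], []
    for row in session.trials.itertuples(index=False):
        d0 = float(row.delay_onset_ms)
        s0 = d0 + float(row.delay_ms)
        s1 = s0 + float(row.stimulus_ms)
        t0 = d0 if alignment == "delay_onset" else s0
        lo, hi = t0 + start, t0 + end
        flag = False
        if restrict_to_epoch:
            epoch_lo, epoch_hi = (d0, s0) if alignment == "delay_onset" else (s0, s1)
            if hi > epoch_hi or lo < epoch_lo:
                flag = True
            lo, hi = max(lo, epoch_lo), min(hi, epoch_hi)
        if hi > rec_end:
            flag = True
            hi = min(hi, rec_end)
        i0, i1 = np.searchsorted(mid, [lo, hi], side="left")
        windows.append(store.activity[:, i0:i1])
        rel_times.append(store.frame_times_ms[i0:i1] - t0)
        incomplete.append(flag)
        tidx.append(int(row.trial_index))
    return TrialAlignedTensor(
        windows=windows,
        trial_index=np.array(tidx, dtype=int),
        incomplete=np.array(incomplete, dtype=bool),
        alignment=alignment,
        window_ms=(float(start), float(end)),
        rel_times_ms=rel_times,
    )


def binned_trial_matrix(
    tensor: TrialAlignedTensor, frame_period_ms: float, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Arrange aligned windows on a common time grid.

    Returns ``(trials x units x n_bins array with NaN where no frame fell in a
    bin, bin-centre times)``.  Bin *b* covers ``[b*T, (b+1)*T)`` relative
    milliseconds where ``T`` is the frame period.
    """
    n_trials = len(tensor)
    n_units = tensor.windows[0].shape[0] if n_trials else 0
    out = np.full((n_trials, n_units, n_bins), np.nan)
    start = tensor.window_ms[0]
    for i, (w, rt) in enumerate(zip(tensor.windows, tensor.rel_times_ms)):
        # bin by the frame's temporal midpoint, matching window membership
        b = np.floor((rt + 0.5 * frame_period_ms - start) / frame_period_ms).astype(int)
        ok = (b >= 0) & (b < n_bins)
        out[i, :, b[ok]] = w[:, ok].T
    centers = start + (np.arange(n_bins) + 0.5) * frame_period_ms
    return out, centers
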