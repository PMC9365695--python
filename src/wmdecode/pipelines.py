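"""End-to-end orchestration helpers tying the generators to the analyses.

These functions wire sessions and activity stores into the feature matrices
the decoding and silencing analyses consume, and run complete simulated
silencing experiments for the two recovery regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .activity import ActivityStore, align_trials
from .axons import behavioral_robustness, feedback_cd_timecourse
from .config import AnalysisConfig
from .session import SessionTable, filter_trials
from .simulate import (
    AxonParams,
    BehaviorParams,
    NeuralParams,
    TaskParams,
    generate_trials,
    simulate_boutons,
    simulate_responses,
)


@dataclass
class DelayFeatures:
    """Delay-epoch feature matrices for one (filtered) session."""

    X: np.ndarray                   # trials x units, full-delay average
    X_early: np.ndarray             # [0, half_split) average
    X_late: np.ndarray              # [half_split, cap) average (NaN if absent)
    ok: np.ndarray                  # trials with >= min_frames delay frames
    late_ok: np.ndarray
    task: np.ndarray
    prev_cue: np.ndarray
    delays_ms: np.ndarray
    outcome: np.ndarray
    silenced_delay_onset: np.ndarray
    frames: np.ndarray              # analysis-trial frames concatenated in time
    tensor: object

    @property
    def wm_cue_mask(self) -> np.ndarray:
        return (self.task == "WM") & np.isin(self.prev_cue, ["A", "B"]) & self.ok


def delay_features(
    session: SessionTable,
    store: ActivityStore,
    cfg: AnalysisConfig | None = None,
    min_frames: int = 2,
    include_stim_frames: bool = True,
) -> DelayFeatures:
    """Delay-averaged features plus early/late-half averages for a session
    already passed through ``filter_trials``."""
    cfg = cfg or AnalysisConfig()
    cap = cfg.analysis_delay_cap_ms
    half = cfg.half_split_ms
    full = align_trials(session, store, "delay_onset", (0.0, cap))
    early = align_trials(session, store, "delay_onset", (0.0, half))
    late = align_trials(session, store, "delay_onset", (half, cap))
    X, ok = full.trial_means(min_frames)
    Xe, _ = early.trial_means(1)
    Xl, late_ok = late.trial_means(1)
    frame_blocks = [w for w, o in zip(full.windows, ok) if o]
    if include_stim_frames:
        stim = align_trials(session, store, "stim_onset", (0.0, half))
        frame_blocks += [w for w, o in zip(stim.windows, ok) if o and w.size]
    frames = np.hstack(frame_blocks).T if frame_blocks else np.zeros((0, store.n_units))
    df = session.trials
    return DelayFeatures(
        X=X, X_early=Xe, X_late=Xl, ok=ok, late_ok=late_ok,
        task=df["task"].to_numpy(),
        prev_cue=df["prev_cue_identity"].to_numpy(),
        delays_ms=df["delay_ms"].to_numpy(),
        outcome=df["outcome"].to_numpy(),
        silenced_delay_onset=(df["opto_epoch"] == "delay_onset").to_numpy(),
        frames=frames,
        tensor=full,
    )


@dataclass
class RegimeResult:
    """One simulated silencing experiment: cue-code disruption per delay half
    and behavioral deficits per delay-length bin."""

    effect_early: float
    effect_late: float
    p_early: float
    p_late: float
    deficit_short: float
    deficit_long: float
    p_short: float
    p_long: float


def silencing_regime_sim(
    recovery_ms: float | None,
    rng: np.random.Generator,
    attenuation: float = 0.8,
    fa_boost: float = 0.4,
    n_neural_trials: int = 1200,
    n_behavior_trials: int = 4000,
    n_axons: int = 30,
    code_amplitude: float = 0.4,
    latent_noise: float = 0.4,
    gamma: float = 1e-4,
) -> RegimeResult:
    """Simulate one silencing experiment under a given recovery regime.

    ``recovery_ms=None`` is the no-recovery regime (cue code and behavior
    disrupted for the whole delay); a finite value (e.g. 1200 ms) lets both
    the feedback cue code and the memory recover before the late delay.
    The same recovery parameter drives the axonal generator and the
    behavioral generator, so the neural and behavioral signatures are linked.
    """
    tp = TaskParams(opto_fraction=0.15, opto_epochs=("delay_onset",),
                    halt_rate=0.0, early_lick_rate=0.0)
    # neural arm: feedback axons under local silencing of the target area
    s_neural = generate_trials(
        n_neural_trials, tp, rng, task_schedule=[("WM", "CW", n_neural_trials)],
        frame_rate_hz=22.78,
    )
    ap = AxonParams(n_axons=n_axons, silencing_cue_attenuation=attenuation,
                    silencing_recovery_ms=recovery_ms)
    np_ = replace(NeuralParams(), n_cells=n_axons, frame_rate_hz=22.78,
                  noise_sigma=latent_noise, code_amplitude=code_amplitude,
                  task_code_scale=0.0)
    from .simulate import _build_activity

    axon_store, _ = _build_activity(
        s_neural, np_, rng,
        silencing=(ap.silencing_cue_attenuation, ap.silencing_recovery_ms),
        unit_prefix="axon", signal_kind="axon",
    )
    f = filter_trials(s_neural, imaging=True)
    feats = delay_features(f, axon_store, include_stim_frames=False)
    m = feats.wm_cue_mask
    fb = feedback_cd_timecourse(
        feats.X_early[m], np.nan_to_num(feats.X_late[m]),
        feats.prev_cue[m], feats.silenced_delay_onset[m],
        gamma=gamma, late_valid=feats.late_ok[m],
    )
    # behavioral arm: silencing raises WM-cue false alarms until recovery
    s_behav = generate_trials(
        n_behavior_trials, tp, rng,
        task_schedule=[("WM", "CW", n_behavior_trials)],
    )
    bp = BehaviorParams(opto_fa_boost=fa_boost, opto_recovery_ms=recovery_ms)
    s_behav = simulate_responses(s_behav, bp, rng)
    fb_beh = filter_trials(s_behav)
    cue_trials = fb_beh.trials[fb_beh.trials["trial_type"] == "cue"]
    br = behavioral_robustness(cue_trials)
    return RegimeResult(
        effect_early=fb.effect_early, effect_late=fb.effect_late,
        p_early=fb.p_early, p_late=fb.p_late,
        deficit_short=br.deficit_short, deficit_long=br.deficit_long,
        p_short=br.p_short, p_long=br.p_long,
    )


def classify_regime(r: RegimeResult) -> str:
    """Label a simulated silencing experiment as 'persistent' (early and late
    disruption with short- and long-delay behavioral deficits), 'transient'
    (early-only disruption, short-only deficit), or 'other'.

    The late/early disruption ratio is thresholded at 1/2 (midway between the
    no-recovery expectation of ~1 and the full-recovery expectation of ~0),
    with a significance gate on the early effect only; a conjunction of null
    non-rejections would cap the attainable classification rate.
    """
    if not (np.isfinite(r.p_early) and r.p_early < 0.05 and r.effect_early > 0):
        return "other"
    cd_ratio = r.effect_late / r.effect_early
    if r.deficit_short <= 0.05:
        return "other"
    beh_persistent = r.deficit_long > 0.05 and r.deficit_long > r.deficit_short / 2
    beh_transient = r.deficit_long < r.deficit_short / 2
    if cd_ratio >= 0.5 and r.p_late < 0.05 and beh_persistent:
        return "persistent"
    if cd_ratio < 0.5 and beh_transient:
        return "transient"
    return "other"
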