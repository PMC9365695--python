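"""Synthetic task, behavior, population and bouton generators.

The generators emulate the statistical structure the downstream analyses
assume: a three-state Markov trial-type process with a mandatory cue after
probes and targets; exponential-plus-offset delay durations capped by uniform
resampling; delay-length-dependent working-memory false alarms; task-agnostic
low-dimensional sequential delay dynamics; sparse high-dimensional task and
cue codes orthogonal to the sequential subspace; axons whose boutons share a
latent trace; and delay-onset silencing that attenuates the cue code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activity import ActivityStore
from .session import SessionTable


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class TaskParams:
    """Trial-sequence statistics of the two-task paradigm."""

    p_cue: float = 0.8
    p_probe: float = 0.1
    p_target: float = 0.1
    delay_mean_ms: float = 800.0
    delay_offset_ms: float = 800.0
    delay_cap_ms: float = 4000.0
    resample_lo_ms: float = 3600.0
    resample_hi_ms: float = 4000.0
    stimulus_median_ms: float = 1967.0
    stimulus_sigma_log: float = 0.2
    opto_fraction: float = 0.08
    opto_epochs: tuple[str, ...] = ("delay_onset", "stim_onset")
    opto_areas: tuple[str, ...] = ("AM",)
    halt_rate: float = 0.02
    early_lick_rate: float = 0.032

    def __post_init__(self) -> None:
        if abs(self.p_cue + self.p_probe + self.p_target - 1.0) > 1e-12:
            raise ValueError("trial-type probabilities must sum to 1")
        if not self.resample_lo_ms < self.resample_hi_ms <= self.delay_cap_ms:
            raise ValueError("need resample_lo < resample_hi <= delay_cap")


@dataclass
class BehaviorParams:
    """Response model: linear-in-delay WM false alarms, fixed-rate otherwise.

    ``opto_fa_boost``/``opto_recovery_ms`` describe the behavioural consequence
    of delay-onset silencing: the WM-cue false-alarm probability is raised by
    the boost unless the memory has recovered by stimulus onset (delays longer
    than the recovery time).  ``opto_recovery_ms=None`` means no recovery.
    """

    fa_base: float = 0.05
    fa_slope_per_s: float = 0.119
    probe_fa: float = 0.10
    hit_rate: float = 0.95
    lapse: float = 0.02
    rt_mean_ms: float = 400.0
    rt_sd_ms: float = 60.0
    rt_shift_wm_ms: float = 163.0
    rt_shift_wm_target_ms: float = 70.0
    opto_fa_boost: float = 0.0
    opto_recovery_ms: float | None = None


@dataclass
class NeuralParams:
    """Population-activity model.

    Activity is a baseline plus (i) sequential Gaussian bumps tiling the delay,
    identical in expectation across tasks, (ii) sparse task and cue codes
    orthogonalized against the bump subspace and active only during WM delays,
    with lognormal trial-to-trial amplitude (CV ``code_trial_cv``) and an exact
    Pearson correlation ``persistence_rho`` between the amplitudes of the two
    delay halves, (iii) a dense low-dimensional stimulus-evoked response with
    an orientation-sign component, and (iv) i.i.d. Gaussian noise, rectified
    at zero.
    """

    n_cells: int = 300
    frame_rate_hz: float = 4.68
    n_seq_bumps: int = 8
    bump_width_ms: float = 300.0
    bump_amplitude: float = 0.4
    code_amplitude: float = 0.1
    task_code_scale: float = 2.0
    code_participation: float = 0.2
    code_trial_cv: float = 0.3
    noise_sigma: float = 0.16
    persistence_rho: float = 0.7
    stim_amplitude: float = 1.2
    stim_code_amplitude: float = 1.2
    stim_decay_ms: float = 800.0
    disc_cue_code_scale: float = 0.0
    baseline: float = 0.4
    rectify: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.code_participation <= 1.0:
            raise ValueError("code_participation must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.persistence_rho <= 1.0:
            raise ValueError("persistence_rho must be in [0, 1]")


@dataclass
class AxonParams:
    n_axons: int = 60
    boutons_per_axon_mean: float = 8.0
    bouton_noise_sigma: float = 0.1
    silencing_cue_attenuation: float = 0.8
    silencing_recovery_ms: float | None = None

    def __post_init__(self) -> None:
        if self.boutons_per_axon_mean < 1:
            raise ValueError("boutons_per_axon_mean must be >= 1")
        if not 0.0 <= self.silencing_cue_attenuation <= 1.0:
            raise ValueError("silencing_cue_attenuation must be in [0, 1]")


# ---------------------------------------------------------------------------
# task sequence
# ---------------------------------------------------------------------------

def sample_delays(n: int, params: TaskParams, rng: np.random.Generator) -> np.ndarray:
    """Delay durations: offset + Exp(mean), capped by uniform resampling.

    Values exceeding the cap are replaced by draws from
    Uniform(resample_lo, resample_hi), keeping the cap's effect on the mean
    small.  Support is [offset, cap].
    """
    x = params.delay_offset_ms + rng.exponential(params.delay_mean_ms, size=n)
    over = x > params.delay_cap_ms
    x[over] = rng.uniform(params.resample_lo_ms, params.resample_hi_ms, size=int(over.sum()))
    return x


def sample_delay(params: TaskParams, rng: np.random.Generator) -> float:
    return float(sample_delays(1, params, rng)[0])


def expected_delay_mean_ms(params: TaskParams) -> float:
    """Closed-form mean of the capped delay distribution."""
    p_over = math.exp(-(params.delay_cap_ms - params.delay_offset_ms) / params.delay_mean_ms)
    uncapped = params.delay_offset_ms + params.delay_mean_ms
    resampled = 0.5 * (params.resample_lo_ms + params.resample_hi_ms)
    over_mean = params.delay_cap_ms + params.delay_mean_ms  # memorylessness
    return uncapped + p_over * (resampled - over_mean)


_ROT_OFFSET = {"CW": -15.0, "CCW": 15.0, "NONE": 0.0}


def default_schedule(n: int) -> list[tuple[str, str, int]]:
    """Four alternating task blocks with rotation blocks out of phase."""
    blocks = [("DISC", "CW"), ("WM", "CCW"), ("DISC", "CCW"), ("WM", "CW")]
    base = n // 4
    sizes = [base, base, base, n - 3 * base]
    return [(t, r, s) for (t, r), s in zip(blocks, sizes)]


def generate_trials(
    n: int,
    params: TaskParams | None = None,
    rng: np.random.Generator | None = None,
    task_schedule: list[tuple[str, str, int]] | None = None,
    mouse_id: str = "sim",
    area: str = "AM",
    frame_rate_hz: float = 4.68,
) -> SessionTable:
    """Generate a trial table (no outcomes yet).

    Trial types follow the Markov rule: after a cue, draw cue/probe/target with
    the stated probabilities; after a probe or a target, a cue is mandatory.
    In the WM task the cue orientation mirrors the current target and switches
    only after a target is presented; in the Discrimination task the cue is
    always the 0-degree-class stimulus.  Probes are 90 degrees in both tasks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or TaskParams()
    rng = rng if rng is not None else np.random.default_rng()
    task_schedule = task_schedule or default_schedule(n)
    tasks, rotations = [], []
    for task, rot, size in task_schedule:
        tasks.extend([task] * size)
        rotations.extend([rot] * size)
    if len(tasks) != n:
        raise ValueError("task_schedule sizes must sum to n")

    delays = sample_delays(n, params, rng)
    stims = params.stimulus_median_ms * np.exp(
        rng.normal(0.0, params.stimulus_sigma_log, size=n)
    )
    type_draw = rng.choice(
        ["cue", "probe", "target"],
        size=n,
        p=[params.p_cue, params.p_probe, params.p_target],
    )
    opto = rng.random(n) < params.opto_fraction
    opto_epoch_draw = rng.choice(list(params.opto_epochs), size=n)
    opto_area_draw = rng.choice(list(params.opto_areas), size=n)
    halted = rng.random(n) < params.halt_rate
    early = rng.random(n) < params.early_lick_rate

    rows = []
    prev_type = "cue"
    prev_cue_id = "NA"
    wm_target_sign = 1.0  # +1 => target +30 base, cue -30 base ("A")
    onset = 0.0
    for i in range(n):
        ttype = "cue" if prev_type in ("probe", "target") else str(type_draw[i])
        rot = _ROT_OFFSET[rotations[i]]
        cue_id = "NA"
        if ttype == "probe":
            ori = 90.0
        elif tasks[i] == "DISC":
            ori = (0.0 if ttype == "cue" else rng.choice([-30.0, 30.0])) + rot
            if ttype == "cue":
                cue_id = "NA"
        else:  # WM
            if ttype == "cue":
                base = -wm_target_sign * 30.0
                cue_id = "A" if base < 0 else "B"
                ori = base + rot
            else:  # target
                ori = wm_target_sign * 30.0 + rot
                wm_target_sign = -wm_target_sign
        rows.append(
            dict(
                trial_index=i,
                task=tasks[i],
                rotation=rotations[i],
                trial_type=ttype,
                cue_identity=cue_id,
                prev_cue_identity=prev_cue_id,
                stimulus_orientation=ori,
                delay_ms=float(delays[i]),
                stimulus_ms=float(stims[i]),
                delay_onset_ms=onset,
                lick_latency_ms=np.nan,
                outcome="NA",
                opto_epoch=str(opto_epoch_draw[i]) if opto[i] else "none",
                opto_area=str(opto_area_draw[i]) if opto[i] else "NA",
                halted=bool(halted[i]),
                early_lick=bool(early[i]),
            )
        )
        onset += float(delays[i]) + float(stims[i])
        prev_cue_id = cue_id if ttype == "cue" else "NA"
        prev_type = ttype
    return SessionTable(
        trials=pd.DataFrame(rows),
        mouse_id=mouse_id,
        area=area,
        frame_rate_hz=frame_rate_hz,
    )


def simulate_responses(
    session: SessionTable, bp: BehaviorParams | None = None,
    rng: np.random.Generator | None = None,
) -> SessionTable:
    """Assign outcomes and lick latencies.

    WM-cue false-alarm probability grows linearly with the trial's preceding
    delay duration; Discrimination-cue and probe responses are
    delay-independent.  Hits occur with probability hit_rate*(1 - lapse)
    within the 1 s response window; WM engagement shifts lick latencies.
    """
    bp = bp or BehaviorParams()
    rng = rng if rng is not None else np.random.default_rng()
    df = session.trials.copy()
    outcomes, latencies = [], []
    for row in df.itertuples(index=False):
        delay_s = row.delay_ms / 1000.0
        wm = row.task == "WM"
        lat = np.nan
        if row.trial_type == "target":
            p = bp.hit_rate * (1.0 - bp.lapse)
            if rng.random() < p:
                out = "hit"
                lat = rng.normal(
                    bp.rt_mean_ms + (bp.rt_shift_wm_target_ms if wm else 0.0),
                    bp.rt_sd_ms,
                )
            else:
                out = "miss"
        else:
            if row.trial_type == "probe":
                p = bp.probe_fa
            elif wm:
                p = bp.fa_base + bp.fa_slope_per_s * delay_s
            else:
                p = bp.fa_base
            if (
                bp.opto_fa_boost > 0
                and row.opto_epoch == "delay_onset"
                and wm
                and row.trial_type == "cue"
                and (bp.opto_recovery_ms is None or row.delay_ms <= bp.opto_recovery_ms)
            ):
                p += bp.opto_fa_boost
            p = min(max(p, 0.0), 1.0)
            if rng.random() < p:
                out = "FA"
                lat = rng.normal(
                    bp.rt_mean_ms + (bp.rt_shift_wm_ms if wm else 0.0), bp.rt_sd_ms
                )
            else:
                out = "CR"
        if np.isfinite(lat):
            lat = float(np.clip(lat, 10.0, 995.0))
        outcomes.append(out)
        latencies.append(lat)
    df["outcome"] = outcomes
    df["lick_latency_ms"] = latencies
    return session.with_trials(df)


# ---------------------------------------------------------------------------
# neural population
# ---------------------------------------------------------------------------

@dataclass
class PopulationGroundTruth:
    """Planted structure of a simulated population, for oracle tests."""

    bump_loadings: np.ndarray       # cells x n_bumps
    task_code: np.ndarray           # unit vector, cells
    cue_code: np.ndarray            # unit vector, cells
    stim_shared: np.ndarray         # dense shared stimulus response direction
    stim_code: np.ndarray           # dense low-D orientation code direction
    amp_task: np.ndarray            # trials x 2 (early, late half amplitudes)
    amp_cue: np.ndarray             # trials x 2


def _correlated_lognormal_pairs(
    n: int, mean: float, cv: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Pairs of lognormal amplitudes with mean ``mean``, coefficient of
    variation ``cv`` and *linear* Pearson correlation exactly ``rho``."""
    if cv <= 0:
        return np.full((n, 2), mean)
    s2 = math.log(1.0 + cv * cv)
    rho_z = math.log(1.0 + rho * (math.exp(s2) - 1.0)) / s2
    z1 = rng.normal(size=n)
    z2 = rho_z * z1 + math.sqrt(max(0.0, 1.0 - rho_z * rho_z)) * rng.normal(size=n)
    s = math.sqrt(s2)
    a = mean * np.exp(s * np.column_stack([z1, z2]) - s2 / 2.0)
    return a


def _orthogonalize(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project v off the column span of basis and renormalize."""
    if basis.size:
        q, _ = np.linalg.qr(basis)
        v = v - q @ (q.T @ v)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("degenerate code direction")
    return v / nrm


def _sparse_direction(
    n_cells: int, participation: float, rng: np.random.Generator
) -> np.ndarray:
    k = max(2, int(round(participation * n_cells)))
    idx = rng.choice(n_cells, size=min(k, n_cells), replace=False)
    v = np.zeros(n_cells)
    v[idx] = rng.normal(size=len(idx))
    return v


def _build_activity(
    session: SessionTable,
    np_: NeuralParams,
    rng: np.random.Generator,
    half_split_ms: float = 1600.0,
    silencing: tuple[float, float | None] | None = None,
    unit_prefix: str = "cell",
    signal_kind: str = "soma",
) -> tuple[ActivityStore, PopulationGroundTruth]:
    df = session.trials
    n_trials = len(df)
    d0 = df["delay_onset_ms"].to_numpy()
    s0 = d0 + df["delay_ms"].to_numpy()
    s1 = s0 + df["stimulus_ms"].to_numpy()
    period = 1000.0 / np_.frame_rate_hz
    t_end = s1[-1]
    frame_times = np.arange(0.0, t_end, period)
    mid = frame_times + period / 2.0

    trial_of = np.searchsorted(d0, mid, side="right") - 1
    trial_of = np.clip(trial_of, 0, n_trials - 1)
    in_delay = (mid >= d0[trial_of]) & (mid < s0[trial_of])
    in_stim = (mid >= s0[trial_of]) & (mid < s1[trial_of])

    n_cells = np_.n_cells
    # sequential bumps: each cell loads one bump, tiling the analysis window
    centers = np.linspace(200.0, 3000.0, np_.n_seq_bumps)
    bump_of_cell = np.arange(n_cells) % np_.n_seq_bumps
    B = np.zeros((n_cells, np_.n_seq_bumps))
    B[np.arange(n_cells), bump_of_cell] = np.abs(rng.normal(1.0, 0.3, size=n_cells))
    B *= np_.bump_amplitude

    u_task = _orthogonalize(
        _sparse_direction(n_cells, np_.code_participation, rng), B
    )
    u_cue = _orthogonalize(
        _sparse_direction(n_cells, np_.code_participation, rng),
        np.column_stack([B, u_task]),
    )
    u0 = np.abs(rng.normal(size=n_cells))
    u0 /= np.linalg.norm(u0)
    u1 = _orthogonalize(rng.normal(size=n_cells), u0[:, None])

    amp_task = _correlated_lognormal_pairs(
        n_trials, np_.code_amplitude, np_.code_trial_cv, np_.persistence_rho, rng
    )
    amp_cue = _correlated_lognormal_pairs(
        n_trials, np_.code_amplitude, np_.code_trial_cv, np_.persistence_rho, rng
    )

    activity = np.full((n_cells, len(frame_times)), float(np_.baseline))

    # delay components (vectorized over delay frames)
    didx = np.flatnonzero(in_delay)
    if didx.size:
        tr = trial_of[didx]
        t_rel = mid[didx] - d0[tr]
        G = np.exp(-0.5 * ((t_rel[:, None] - centers[None, :]) / np_.bump_width_ms) ** 2)
        activity[:, didx] += B @ G.T

        late = t_rel >= half_split_ms
        half = late.astype(int)
        wm = (df["task"].to_numpy() == "WM")[tr]
        c_task = np.where(wm, np_.task_code_scale * amp_task[tr, half], 0.0)

        prev = df["prev_cue_identity"].to_numpy()
        sign = np.where(prev == "B", 1.0, np.where(prev == "A", -1.0, 0.0))[tr]
        scale = np.where(wm, 1.0, np_.disc_cue_code_scale)
        c_cue = sign * scale * amp_cue[tr, half]
        if silencing is not None:
            att, recovery = silencing
            sil_trial = (df["opto_epoch"].to_numpy() == "delay_onset")[tr]
            active = sil_trial if recovery is None else (sil_trial & (t_rel < recovery))
            c_cue = np.where(active, c_cue * (1.0 - att), c_cue)
        activity[:, didx] += np.outer(u_task, c_task) + np.outer(u_cue, c_cue)

    # stimulus components
    sidx = np.flatnonzero(in_stim)
    if sidx.size:
        tr = trial_of[sidx]
        t_rel = mid[sidx] - s0[tr]
        g = np.exp(-t_rel / np_.stim_decay_ms)
        ori = df["stimulus_orientation"].to_numpy()[tr]
        is_probe = (df["trial_type"].to_numpy() == "probe")[tr]
        sign = np.where(is_probe, 0.0, np.sign(ori))
        activity[:, sidx] += np.outer(u0, np_.stim_amplitude * g)
        activity[:, sidx] += np.outer(u1, np_.stim_code_amplitude * sign * g)

    if np_.noise_sigma > 0:
        activity += rng.normal(0.0, np_.noise_sigma, size=activity.shape)
    if np_.rectify:
        np.clip(activity, 0.0, None, out=activity)

    store = ActivityStore(
        activity=activity,
        frame_times_ms=frame_times,
        unit_ids=[f"{unit_prefix}{i:04d}" for i in range(n_cells)],
        signal_kind=signal_kind,
        frame_rate_hz=np_.frame_rate_hz,
    )
    truth = PopulationGroundTruth(
        bump_loadings=B, task_code=u_task, cue_code=u_cue,
        stim_shared=u0, stim_code=u1, amp_task=amp_task, amp_cue=amp_cue,
    )
    return store, truth


def simulate_population(
    session: SessionTable,
    np_: NeuralParams | None = None,
    rng: np.random.Generator | None = None,
    half_split_ms: float = 1600.0,
) -> tuple[ActivityStore, PopulationGroundTruth]:
    """Simulate a somatic population for a session (see NeuralParams)."""
    np_ = np_ or NeuralParams()
    rng = rng if rng is not None else np.random.default_rng()
    return _build_activity(session, np_, rng, half_split_ms=half_split_ms)


def simulate_boutons(
    session: SessionTable,
    ap: AxonParams | None = None,
    np_: NeuralParams | None = None,
    rng: np.random.Generator | None = None,
    half_split_ms: float = 1600.0,
) -> tuple[ActivityStore, np.ndarray, ActivityStore, PopulationGroundTruth]:
    """Simulate axonal boutons with shared per-axon latent traces.

    Each axon carries a latent trace (bumps plus cue code); each of its boutons
    is the latent trace plus i.i.d. noise.  On trials silenced at delay onset
    the cue-code amplitude is multiplied by (1 - silencing_cue_attenuation)
    from the delay onset, recovering after ``silencing_recovery_ms`` if finite.

    Returns (bouton store, ground-truth axon label per bouton, axon-latent
    store, planted-structure record).
    """
    ap = ap or AxonParams()
    # the axon-latent "noise" is a private per-axon signal shared by all of the
    # axon's boutons; it is what makes the clustering identifiable, and its sd
    # relative to bouton_noise_sigma sets the bouton SNR (default 0.5/0.1 = 5).
    np_ = np_ or replace(NeuralParams(), n_cells=ap.n_axons, frame_rate_hz=22.78,
                         noise_sigma=0.5)
    if np_.n_cells != ap.n_axons:
        np_ = replace(np_, n_cells=ap.n_axons)
    rng = rng if rng is not None else np.random.default_rng()
    axon_store, truth = _build_activity(
        session, np_, rng,
        half_split_ms=half_split_ms,
        silencing=(ap.silencing_cue_attenuation, ap.silencing_recovery_ms),
        unit_prefix="axon", signal_kind="axon",
    )
    counts = np.maximum(1, rng.poisson(ap.boutons_per_axon_mean, size=ap.n_axons))
    labels = np.repeat(np.arange(ap.n_axons), counts)
    boutons = axon_store.activity[labels] + rng.normal(
        0.0, ap.bouton_noise_sigma, size=(len(labels), axon_store.n_frames)
    )
    bouton_store = ActivityStore(
        activity=boutons,
        frame_times_ms=axon_store.frame_times_ms,
        unit_ids=[f"bouton{i:05d}" for i in range(len(labels))],
        signal_kind="bouton",
        frame_rate_hz=np_.frame_rate_hz,
    )
    return bouton_store, labels, axon_store, truth
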