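"""Responsiveness criteria and response-latency estimation.

Units enter the population analyses only if they pass a conjunctive
responsiveness criterion: the post-versus-pre onset effect size must exceed a
threshold AND differ significantly in a paired t-test across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .activity import TrialAlignedTensor


class InsufficientDataError(ValueError):
    pass


@dataclass
class ResponsivenessResult:
    unit_id: str
    kind: str                    # "delay" or "stimulus"
    effect_size: float           # mean(post) - mean(pre) across trials
    p_value: float
    responsive: bool


def is_responsive(
    pre: TrialAlignedTensor,
    post: TrialAlignedTensor,
    unit_ids: list[str],
    kind: str = "delay",
    threshold: float = 0.2,
    alpha: float = 0.01,
    min_trials: int = 10,
) -> list[ResponsivenessResult]:
    """Conjunctive responsiveness test for every unit.

    ``pre`` and ``post`` are trial-aligned windows around the same onsets
    (e.g. the 800 ms before and after delay onset).  A unit is responsive iff
    its effect size exceeds ``threshold`` (0.2 deconvolved dF/F0 by default)
    and the paired two-sided t-test across trials is significant at ``alpha``.
    """
    pre_m, pre_ok = pre.trial_means()
    post_m, post_ok = post.trial_means()
    usable = pre_ok & post_ok & ~pre.incomplete & ~post.incomplete
    if usable.sum() < min_trials:
        raise InsufficientDataError(
            f"only {int(usable.sum())} trials with both windows complete"
        )
    a, b = post_m[usable], pre_m[usable]
    effects = a.mean(axis=0) - b.mean(axis=0)
    t, p = stats.ttest_rel(a, b, axis=0)
    out = []
    for i, uid in enumerate(unit_ids):
        resp = bool(effects[i] > threshold and p[i] < alpha)
        out.append(ResponsivenessResult(uid, kind, float(effects[i]), float(p[i]), resp))
    return out


def is_axon_delay_responsive(
    delay: TrialAlignedTensor,
    baseline: TrialAlignedTensor,
    unit_ids: list[str],
    z_mean: np.ndarray,
    z_sd: np.ndarray,
    threshold: float = 0.2,
    alpha: float = 0.01,
    window_ms: float = 1000.0,
    step_ms: float = 200.0,
    min_trials: int = 10,
) -> list[ResponsivenessResult]:
    """Delay responsiveness for axons: any sliding 1 s delay window must exceed
    the last second of the preceding stimulus by ``threshold`` z-scored units
    with paired-t significance ``alpha`` (Bonferroni-corrected over windows;
    raw per-window p-values are folded into the reported minimum).

    ``z_mean``/``z_sd`` are the session-wide per-unit statistics used to
    z-score activity.
    """
    z_sd = np.where(z_sd > 0, z_sd, 1.0)
    base_m, base_ok = baseline.trial_means()
    base_z = (base_m - z_mean) / z_sd

    starts = []
    s = delay.window_ms[0]
    while s + window_ms <= delay.window_ms[1]:
        starts.append(s)
        s += step_ms
    if not starts:
        raise InsufficientDataError("delay window shorter than 1 s")

    n_units = len(unit_ids)
    best_eff = np.full(n_units, -np.inf)
    best_p = np.full(n_units, np.nan)
    any_pass = np.zeros(n_units, dtype=bool)
    n_windows = len(starts)
    tested = 0
    for s in starts:
        rows = []
        base_rows = []
        for i, (w, rt) in enumerate(zip(delay.windows, delay.rel_times_ms)):
            if not base_ok[i]:
                continue
            sel = (rt >= s) & (rt < s + window_ms)
            if sel.any():
                rows.append((w[:, sel].mean(axis=1) - z_mean) / z_sd)
                base_rows.append(base_z[i])
        if len(rows) < min_trials:
            continue
        tested += 1
        a = np.asarray(rows)
        b = np.asarray(base_rows)
        eff = a.mean(axis=0) - b.mean(axis=0)
        _, p = stats.ttest_rel(a, b, axis=0)
        p_adj = np.minimum(1.0, p * n_windows)
        passing = (eff > threshold) & (p_adj < alpha)
        any_pass |= passing
        upd = eff > best_eff
        best_p = np.where(upd, p_adj, best_p)
        best_eff = np.maximum(best_eff, eff)
    if tested == 0:
        raise InsufficientDataError("no delay window with enough complete trials")
    return [
        ResponsivenessResult(uid, "delay", float(best_eff[i]), float(best_p[i]),
                             bool(any_pass[i]))
        for i, uid in enumerate(unit_ids)
    ]


@dataclass
class LatencyResult:
    unit_id: str
    latency_ms: float
    fit_ok: bool
    fit_params: tuple[float, float, float]  # amplitude, mean, width
    wide: bool = False


def _gauss(t, a, mu, w, c):
    return a * np.exp(-0.5 * ((t - mu) / w) ** 2) + c


def latency(
    tensor: TrialAlignedTensor,
    unit_ids: list[str],
    frame_period_ms: float,
    min_trials: int = 20,
) -> list[LatencyResult]:
    """Response latency per unit from a Gaussian fit to the odd-trial average.

    Odd-numbered trials estimate the latency (the fitted Gaussian mean); even
    trials are reserved for display averages, so sorting is cross-validated.
    ``fit_ok`` requires convergence, a mean inside the analysis window, and a
    width between one frame and the window length.
    """
    if len(tensor) < min_trials:
        raise InsufficientDataError(f"need >= {min_trials} trials")
    odd = tensor.trial_index % 2 == 1
    lo, hi = tensor.window_ms
    n_bins = int(round((hi - lo) / frame_period_ms))
    grid = lo + (np.arange(n_bins) + 0.5) * frame_period_ms
    n_units = tensor.windows[0].shape[0]
    acc = np.zeros((n_units, n_bins))
    cnt = np.zeros(n_bins)
    for i, (w, rt) in enumerate(zip(tensor.windows, tensor.rel_times_ms)):
        if not odd[i]:
            continue
        b = np.floor((rt - lo) / frame_period_ms).astype(int)
        ok = (b >= 0) & (b < n_bins)
        acc[:, b[ok]] += w[:, ok]
        cnt[b[ok]] += 1
    use = cnt > 0
    avg = acc[:, use] / cnt[use]
    t = grid[use]
    out = []
    for i, uid in enumerate(unit_ids):
        y = avg[i]
        p0 = [y.max() - y.min(), t[int(np.argmax(y))], (hi - lo) / 6.0, y.min()]
        ok = True
        try:
            popt, _ = optimize.curve_fit(_gauss, t, y, p0=p0, maxfev=2000)
        except (RuntimeError, ValueError):
            ok = False
            popt = [np.nan] * 4
        a, mu, w_, c = popt
        w_ = abs(w_)
        if ok:
            ok = (lo <= mu <= hi) and (frame_period_ms <= w_ <= (hi - lo)) and a > 0
        wide = bool(ok and w_ > (hi - lo) / 2.0)
        out.append(LatencyResult(uid, float(mu) if ok else np.nan, ok,
                                 (float(a), float(mu), float(w_)), wide))
    return out


def sort_for_display(
    tensor: TrialAlignedTensor,
    unit_ids: list[str],
    latencies: list[LatencyResult],
    tasks: np.ndarray,
    frame_period_ms: float,
) -> dict[str, np.ndarray]:
    """Even-trial averages per task, rows normalized to [0, 1] per unit and
    ordered by response latency (ties broken by unit id); the same ordering is
    used for both task panels.  Returns {"order": indices, task: matrix}."""
    lat = {r.unit_id: (r.latency_ms if r.fit_ok else np.inf) for r in latencies}
    order = sorted(range(len(unit_ids)), key=lambda i: (lat[unit_ids[i]], unit_ids[i]))
    even = tensor.trial_index % 2 == 0
    lo, hi = tensor.window_ms
    n_bins = int(round((hi - lo) / frame_period_ms))
    out: dict[str, np.ndarray] = {"order": np.array(order, dtype=int)}
    n_units = len(unit_ids)
    for task in ("DISC", "WM"):
        acc = np.zeros((n_units, n_bins))
        cnt = np.zeros(n_bins)
        for i, (w, rt) in enumerate(zip(tensor.windows, tensor.rel_times_ms)):
            if not even[i] or tasks[i] != task:
                continue
            b = np.floor((rt - lo) / frame_period_ms).astype(int)
            okb = (b >= 0) & (b < n_bins)
            acc[:, b[okb]] += w[:, okb]
            cnt[b[okb]] += 1
        avg = np.divide(acc, np.maximum(cnt, 1)[None, :])
        rng_ = avg.max(axis=1) - avg.min(axis=1)
        rng_[rng_ == 0] = 1.0
        norm = (avg - avg.min(axis=1, keepdims=True)) / rng_[:, None]
        out[task] = norm[order]
    return out
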