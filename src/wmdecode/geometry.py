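"""Pooled pseudo-population PCA, task-split trajectories, distance-vs-null
statistics, and eigenspectrum comparison.

The pooled matrix trial-averages the delay and stimulus responses of all
active cells across experiments and concatenates the two epochs in time; PCA
over the time dimension of that matrix defines the shared low-dimensional
basis onto which per-task activity is projected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .activity import ActivityStore, align_trials, binned_trial_matrix
from .session import SessionTable

DELAY_GROUPS_MS = ((800.0, 1600.0), (1600.0, 2400.0), (2400.0, 3200.0))


@dataclass
class ExperimentActivity:
    """One experiment's filtered session and activity, plus precomputed
    per-trial binned tensors on the common grids."""

    session: SessionTable
    store: ActivityStore
    delay_tensor: np.ndarray        # trials x cells x T_delay (NaN padded)
    stim_tensor: np.ndarray         # trials x cells x T_stim
    delay_times_ms: np.ndarray
    stim_times_ms: np.ndarray

    @property
    def tasks(self) -> np.ndarray:
        return self.session.trials["task"].to_numpy()


def prepare_experiment(
    session: SessionTable,
    store: ActivityStore,
    delay_cap_ms: float = 3200.0,
    stim_window_ms: float = 1600.0,
) -> ExperimentActivity:
    """Cut per-trial delay- and stimulus-aligned windows onto common grids."""
    period = store.frame_period_ms
    dten = align_trials(session, store, "delay_onset", (0.0, delay_cap_ms))
    sten = align_trials(session, store, "stim_onset", (0.0, stim_window_ms))
    nd = int(round(delay_cap_ms / period))
    ns = int(round(stim_window_ms / period))
    D, dt = binned_trial_matrix(dten, period, nd)
    S, st = binned_trial_matrix(sten, period, ns)
    return ExperimentActivity(session, store, D, S, dt, st)


def pool_trial_averages(
    experiments: list[ExperimentActivity],
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Cells x timepoints pooled trial-average matrix.

    Per cell: the trial-averaged delay response concatenated with the
    trial-averaged stimulus response; cells stacked across experiments as a
    pseudo-population.  Time bins with no covering trial in *any* experiment
    are dropped from the common axis.  Returns (matrix, time axis labels,
    (experiment, unit) refs).
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        blocks, refs = [], []
        for e, exp in enumerate(experiments):
            avg_d = np.nanmean(exp.delay_tensor, axis=0)
            avg_s = np.nanmean(exp.stim_tensor, axis=0)
            blocks.append(np.concatenate([avg_d, avg_s], axis=1))
            refs.extend((e, u) for u in range(exp.store.n_units))
    M = np.vstack(blocks)
    times = np.concatenate(
        [experiments[0].delay_times_ms, experiments[0].stim_times_ms]
    )
    good = ~np.isnan(M).any(axis=0)
    return M[:, good], times[good], refs


def fit_pcs(matrix: np.ndarray, n_components: int | None = None) -> PCA:
    """Mean-centered PCA over the time dimension of a cells x time matrix.

    Components live in cell space; variance fractions are non-increasing and
    sum to at most 1.  Rank-deficient input simply yields trailing
    zero-variance components.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need more than one timepoint")
    pca = PCA(n_components=n_components)
    pca.fit(matrix.T)
    return pca


def _half_normal_smooth(x: np.ndarray, sigma_ms: float, period_ms: float) -> np.ndarray:
    """Causal half-normal filter along the last axis (display only)."""
    n = max(1, int(np.ceil(3 * sigma_ms / period_ms)))
    t = np.arange(n + 1) * period_ms
    k = np.exp(-0.5 * (t / sigma_ms) ** 2)
    k /= k.sum()
    out = np.empty_like(x)
    pad = np.concatenate([np.repeat(x[..., :1], n, axis=-1), x], axis=-1)
    for i in range(x.shape[-1]):
        out[..., i] = (pad[..., i : i + n + 1] * k[::-1]).sum(axis=-1)
    return out


@dataclass
class TrajectorySet:
    projections: dict[tuple[str, int], np.ndarray]  # (task, group) -> time x 3
    times_ms: dict[tuple[str, int], np.ndarray]
    variance_explained: np.ndarray
    delay_groups: tuple = DELAY_GROUPS_MS


def project_trajectories(
    experiments: list[ExperimentActivity],
    pca: PCA,
    refs: list[tuple[int, int]],
    smooth_sigma_ms: float | None = None,
) -> TrajectorySet:
    """Trial-averaged per-task trajectories in PC1-3, split into three delay
    duration groups; each group only uses trials whose delay is at least the
    group's minimum stimulus-onset time.  Smoothing (causal half-normal,
    sigma 100 ms typical) is a display option; the statistics path never
    smooths."""
    period = experiments[0].store.frame_period_ms
    positions = _ref_positions(refs, len(experiments))
    projections, times = {}, {}
    for g, (glo, ghi) in enumerate(DELAY_GROUPS_MS):
        for task in ("DISC", "WM"):
            per_cell, rows = [], []
            for e, exp in enumerate(experiments):
                delays = exp.session.trials["delay_ms"].to_numpy()
                sel = (exp.tasks == task) & (delays >= glo) & (delays < ghi)
                if not sel.any():
                    continue
                nt = int(round(glo / period))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    avg_d = np.nanmean(exp.delay_tensor[sel][:, :, :nt], axis=0)
                    avg_s = np.nanmean(exp.stim_tensor[sel], axis=0)
                per_cell.append(np.concatenate([avg_d, avg_s], axis=1))
                rows.extend(positions[e])
            if not per_cell:
                warnings.warn(f"no trials for task {task} delay group {g}")
                continue
            M = np.vstack(per_cell)
            good = ~np.isnan(M).any(axis=0)
            M = M[:, good]
            if smooth_sigma_ms is not None:
                M = _half_normal_smooth(M, smooth_sigma_ms, period)
            rows = np.asarray(rows, dtype=int)
            proj = (M - pca.mean_[rows, None]).T @ pca.components_[:3, rows].T
            projections[(task, g)] = proj
            nt = int(round(glo / period))
            t_axis = np.concatenate(
                [experiments[0].delay_times_ms[:nt],
                 glo + experiments[0].stim_times_ms]
            )[good]
            times[(task, g)] = t_axis
    return TrajectorySet(projections, times,
                         pca.explained_variance_ratio_[:3])


def _ref_positions(refs: list[tuple[int, int]], n_experiments: int) -> list[list[int]]:
    """Row positions of each experiment's cells inside the pooled matrix."""
    positions: list[list[int]] = [[] for _ in range(n_experiments)]
    for i, (e, _) in enumerate(refs):
        positions[e].append(i)
    return positions


@dataclass
class DistanceResult:
    times_ms: np.ndarray
    distance: np.ndarray
    null_ci: np.ndarray             # (T, 2) 95% interval of the shuffled null
    p_values: np.ndarray
    alpha_bonferroni: float
    per_experiment: np.ndarray      # experiments x T


def _exp_features(exp: ExperimentActivity) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial concatenated delay+stimulus tensors, zero-filled with masks."""
    A = np.concatenate([exp.delay_tensor, exp.stim_tensor], axis=2)
    mask = ~np.isnan(A[:, 0, :])
    return np.nan_to_num(A, nan=0.0), mask


def _task_distance(
    A0: np.ndarray, mask: np.ndarray, labels: np.ndarray, V3: np.ndarray
) -> np.ndarray:
    """Euclidean distance in PC1-3 between task-mean activities per timepoint."""
    out = np.full(A0.shape[2], np.nan)
    means = []
    for task in ("DISC", "WM"):
        sel = labels == task
        cnt = mask[sel].sum(axis=0)
        s = A0[sel].sum(axis=0)                 # cells x T
        with np.errstate(invalid="ignore", divide="ignore"):
            m = s / cnt[None, :]
        means.append((m, cnt))
    (ma, ca), (mb, cb) = means
    ok = (ca > 0) & (cb > 0)
    diff = (ma - mb)[:, ok]
    out[ok] = np.linalg.norm(V3 @ diff, axis=0)
    return out


def trajectory_distance_with_null(
    experiments: list[ExperimentActivity],
    pca: PCA,
    refs: list[tuple[int, int]] | None = None,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> DistanceResult:
    """Task-trajectory Euclidean distance against a trial-shuffled null.

    Per experiment the unsmoothed single-trial activity (delay plus stimulus,
    trials x cells x time) is averaged per task, projected on PC1-3 of the
    pooled basis, and the per-timepoint distance between task means is taken;
    distances are averaged across experiments.  The null shuffles task labels
    across trials within experiment; significance is a per-timepoint two-sided
    test at the Bonferroni-corrected level alpha / n_timepoints.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles: null CI will be unstable")
    if refs is None:
        if pca.components_.shape[1] != experiments[0].store.n_units:
            raise ValueError("refs required when PCA was fit on pooled cells")
        Vs = [pca.components_[:3]] * len(experiments)
    else:
        positions = _ref_positions(refs, len(experiments))
        Vs = [pca.components_[:3, pos] for pos in positions]
    feats = [_exp_features(e) for e in experiments]
    labels = [e.tasks for e in experiments]
    data = np.array([
        _task_distance(A0, m, lab, V3)
        for (A0, m), lab, V3 in zip(feats, labels, Vs)
    ])
    null = np.empty((n_shuffles, len(experiments), data.shape[1]))
    for s in range(n_shuffles):
        for e, ((A0, m), lab) in enumerate(zip(feats, labels)):
            null[s, e] = _task_distance(A0, m, rng.permutation(lab), Vs[e])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        data_mean = np.nanmean(data, axis=0)
        null_mean = np.nanmean(null, axis=1)          # shuffles x T
        ci = np.nanpercentile(null_mean, [2.5, 97.5], axis=0).T
        T = int(np.isfinite(data_mean).sum())
        a_bonf = alpha / max(T, 1)
        p = np.full(data.shape[1], np.nan)
        if len(experiments) > 1:
            null_e_mean = np.nanmean(null, axis=0)     # experiments x T
            diff = data - null_e_mean
            for t in range(diff.shape[1]):
                col = diff[:, t]
                col = col[np.isfinite(col)]
                if len(col) > 1 and col.std() > 0:
                    p[t] = stats.ttest_1samp(col, 0.0).pvalue
        else:
            for t in range(data.shape[1]):
                if np.isfinite(data_mean[t]):
                    nm = null_mean[:, t]
                    nm = nm[np.isfinite(nm)]
                    ge = (nm >= data_mean[t]).mean()
                    p[t] = 2 * min(ge, 1 - ge) + 1.0 / (len(nm) + 1)
                    p[t] = min(p[t], 1.0)
    times = np.concatenate(
        [experiments[0].delay_times_ms,
         experiments[0].delay_times_ms[-1] + experiments[0].stim_times_ms]
    )
    return DistanceResult(times, data_mean, ci, p, a_bonf, data)


@dataclass
class EigenspectrumComparison:
    eigvals_a: np.ndarray
    eigvals_b: np.ndarray
    null_ci: np.ndarray             # (ranks, 2) CI of shuffled |difference|
    significant: np.ndarray


def eigenspectrum_compare(
    Xa: np.ndarray,
    Xb: np.ndarray,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
) -> EigenspectrumComparison:
    """Rank-matched comparison of single-trial delay-activity covariance
    eigenvalues between two conditions.

    Trial counts are equalized by subsampling the larger set; the null
    distribution of per-rank eigenvalue differences comes from shuffling the
    condition labels of the pooled trials.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = min(len(Xa), len(Xb))
    Xa = Xa[rng.permutation(len(Xa))[:n]]
    Xb = Xb[rng.permutation(len(Xb))[:n]]

    def spectrum(X):
        C = np.cov(X, rowvar=False, ddof=1)
        return np.sort(np.linalg.eigvalsh(C))[::-1]

    ea, eb = spectrum(Xa), spectrum(Xb)
    obs = np.abs(ea - eb)
    pooled = np.vstack([Xa, Xb])
    null = np.empty((n_shuffles, len(ea)))
    for s in range(n_shuffles):
        idx = rng.permutation(2 * n)
        null[s] = np.abs(spectrum(pooled[idx[:n]]) - spectrum(pooled[idx[n:]]))
    ci = np.percentile(null, [2.5, 97.5], axis=0).T
    return EigenspectrumComparison(ea, eb, ci, obs > ci[:, 1])
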