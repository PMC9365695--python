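"""Psychometrics: outcome classification, d-prime, response curves, reaction
times, and optogenetic-silencing effect tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

RESPONSE_WINDOW_MS = 1000.0


class InsufficientDataError(ValueError):
    pass


def classify_outcome(trial_type: str, lick_latency_ms: float | None) -> str:
    """Outcome from trial type and lick latency (1 s response window).

    Targets are go stimuli (hit/miss); cues and probes are no-go (FA/CR).
    A lick outside the response window counts as no response.
    """
    lat = lick_latency_ms
    licked = lat is not None and np.isfinite(lat) and lat < RESPONSE_WINDOW_MS
    if licked and lat < 0:
        raise ValueError("negative lick latency")
    if trial_type == "target":
        return "hit" if licked else "miss"
    if trial_type in ("cue", "probe"):
        return "FA" if licked else "CR"
    raise ValueError(f"unknown trial_type {trial_type!r}")


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Signal-detection sensitivity, Phi^-1(hit) - Phi^-1(FA).

    A hit rate of 1 or FA rate of 0 yields +inf; callers treat infinities as
    non-existent data points.
    """
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def _incorrect_mask(df: pd.DataFrame) -> np.ndarray:
    return df["outcome"].isin(["FA", "miss"]).to_numpy()


@dataclass
class QuartileDprime:
    edges_ms: np.ndarray            # 5 quartile edges of the delay distribution
    dprime: np.ndarray              # pooled d' per quartile (NaN if infinite/missing)
    per_mouse: pd.DataFrame | None  # mouse x quartile d' table when >1 mouse
    adjacent_p: list[float | None]  # signed-rank p between adjacent quartiles


def dprime_by_delay_quartile(trials: pd.DataFrame) -> QuartileDprime:
    """d-prime split by delay-length quartile.

    Quartile edges come from the empirical delay distribution of the included
    (cue and target) trials.  Quartiles where every target was hit give an
    infinite d' and are reported as missing.  With multiple mice, adjacent
    quartiles are compared by per-mouse two-sided signed-rank tests.
    """
    df = trials[trials["trial_type"].isin(["cue", "target"])]
    if df.empty:
        raise InsufficientDataError("no cue/target trials")
    edges = np.quantile(df["delay_ms"].to_numpy(), [0, 0.25, 0.5, 0.75, 1.0])
    q = np.clip(np.searchsorted(edges[1:-1], df["delay_ms"].to_numpy(), side="right"), 0, 3)

    def _dp(sub: pd.DataFrame) -> float:
        t = sub[sub["trial_type"] == "target"]
        c = sub[sub["trial_type"] == "cue"]
        if len(t) == 0 or len(c) == 0:
            return np.nan
        d = dprime((t["outcome"] == "hit").mean(), (c["outcome"] == "FA").mean())
        return d if np.isfinite(d) else np.nan

    pooled = np.array([_dp(df[q == k]) for k in range(4)])

    per_mouse = None
    adjacent_p: list[float | None] = [None, None, None]
    if "mouse_id" in df.columns and df["mouse_id"].nunique() > 1:
        rows = {}
        for m, sub in df.groupby("mouse_id"):
            qm = q[df["mouse_id"].to_numpy() == m]
            rows[m] = [_dp(sub[qm == k]) for k in range(4)]
        per_mouse = pd.DataFrame.from_dict(rows, orient="index", columns=range(4))
        for k in range(3):
            a, b = per_mouse[k].to_numpy(), per_mouse[k + 1].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() >= 5 and np.any(a[ok] != b[ok]):
                adjacent_p[k] = float(stats.wilcoxon(a[ok], b[ok]).pvalue)
    return QuartileDprime(edges_ms=edges, dprime=pooled, per_mouse=per_mouse,
                          adjacent_p=adjacent_p)


@dataclass
class PsychometricCurve:
    bin_edges_ms: np.ndarray
    bin_centers_ms: np.ndarray
    rate: np.ndarray
    ci95: np.ndarray                # (bins, 2) Clopper-Pearson
    n: np.ndarray
    slope_pct_per_s: float          # weighted least-squares linear slope
    slope_se_pct_per_s: float


def response_curve(trials: pd.DataFrame, bin_ms: float = 100.0) -> PsychometricCurve:
    """Per-delay-bin response probability with Clopper-Pearson 95% CI, plus a
    weighted least-squares linear slope in percent per second.

    The caller selects the trials (e.g. WM-task cues); "response" means any
    lick in the response window (outcome FA or hit).
    """
    delays = trials["delay_ms"].to_numpy()
    licked = trials["outcome"].isin(["FA", "hit"]).to_numpy()
    lo = np.floor(delays.min() / bin_ms) * bin_ms
    hi = np.ceil(delays.max() / bin_ms) * bin_ms
    n_bins = max(1, int(round((hi - lo) / bin_ms)))
    edges = lo + np.arange(n_bins + 1) * bin_ms
    idx = np.clip(np.digitize(delays, edges) - 1, 0, len(edges) - 2)
    n = np.bincount(idx, minlength=len(edges) - 1)
    k = np.bincount(idx, weights=licked.astype(float), minlength=len(edges) - 1)
    keep = n > 0
    n, k = n[keep], k[keep]
    centers = ((edges[:-1] + edges[1:]) / 2.0)[keep]
    rate = k / n
    lo95, hi95 = proportion_confint(k, n, alpha=0.05, method="beta")
    ci = np.column_stack([lo95, hi95])
    if len(n) >= 2:
        x = centers / 1000.0
        W = np.diag(n.astype(float))
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(W) @ rate, rcond=None)
        resid = rate - X @ beta
        dof = max(len(n) - 2, 1)
        s2 = (n * resid**2).sum() / dof
        cov = s2 * np.linalg.inv(X.T @ W @ X)
        slope, se = 100.0 * beta[1], 100.0 * np.sqrt(cov[1, 1])
    else:
        slope, se = np.nan, np.nan
    return PsychometricCurve(
        bin_edges_ms=edges, bin_centers_ms=centers, rate=rate, ci95=ci, n=n,
        slope_pct_per_s=float(slope), slope_se_pct_per_s=float(se),
    )


@dataclass
class RtPeakLag:
    peak_ms: dict[str, float]
    lag_ms: float                   # WM peak minus Discrimination peak
    bin_ms: float


def rt_peak_lag(trials: pd.DataFrame, bin_ms: float = 1000.0 / 60.0,
                min_licks: int = 50) -> RtPeakLag:
    """Peak (mode-bin) reaction time per task and the WM - DISC lag.

    Histograms are binned at the display frame period (16.67 ms) and
    normalized per task; the peak is the centre of the mode bin.
    """
    peaks = {}
    edges = np.arange(0.0, RESPONSE_WINDOW_MS + bin_ms, bin_ms)
    for task in ("DISC", "WM"):
        lat = trials.loc[trials["task"] == task, "lick_latency_ms"].to_numpy()
        lat = lat[np.isfinite(lat) & (lat < RESPONSE_WINDOW_MS)]
        if len(lat) < min_licks:
            raise InsufficientDataError(f"fewer than {min_licks} licks for task {task}")
        h, _ = np.histogram(lat, bins=edges)
        b = int(np.argmax(h))
        peaks[task] = float((edges[b] + edges[b + 1]) / 2.0)
    return RtPeakLag(peak_ms=peaks, lag_ms=peaks["WM"] - peaks["DISC"], bin_ms=bin_ms)


@dataclass
class OptoEffectRow:
    area: str
    epoch: str
    task: str
    trial_type: str
    rate_diff_pp: float             # silenced minus control incorrect rate, pp
    ci95: tuple[float, float]       # Clopper-Pearson CI of the silenced rate
    fisher_p: float
    fisher_p_bonferroni: float
    n_control: int
    n_silenced: int
    testable: bool


def opto_effect_table(trials: pd.DataFrame) -> tuple[list[OptoEffectRow], pd.DataFrame]:
    """Per-stratum silencing effects and a performance map.

    For each (area, epoch, task, trial type) stratum: the difference of the
    incorrect-response rate (FA for cues/probes, miss for targets) between
    silenced and control trials, a Clopper-Pearson 95% CI on the silenced rate,
    and a two-sided Fisher exact p on the 2x2 response table.  p-values are
    Bonferroni-adjusted across trial types within (area, epoch, task).
    Performance = 100 - FA% - miss% per (area, epoch, task), for both arms.
    """
    control = trials[trials["opto_epoch"] == "none"]
    silenced = trials[trials["opto_epoch"] != "none"]
    rows: list[OptoEffectRow] = []
    perf_rows = []
    for (area, epoch), sil_ae in silenced.groupby(["opto_area", "opto_epoch"]):
        for task in sorted(set(sil_ae["task"])):
            group_rows = []
            for tt in ("cue", "probe", "target"):
                s = sil_ae[(sil_ae["task"] == task) & (sil_ae["trial_type"] == tt)]
                c = control[(control["task"] == task) & (control["trial_type"] == tt)]
                if len(s) == 0 or len(c) == 0:
                    group_rows.append(OptoEffectRow(
                        area, epoch, task, tt, np.nan, (np.nan, np.nan),
                        np.nan, np.nan, len(c), len(s), testable=False))
                    continue
                ks, kc = int(_incorrect_mask(s).sum()), int(_incorrect_mask(c).sum())
                table = [[ks, len(s) - ks], [kc, len(c) - kc]]
                p = float(stats.fisher_exact(table, alternative="two-sided")[1])
                lo, hi = proportion_confint(ks, len(s), alpha=0.05, method="beta")
                diff = 100.0 * (ks / len(s) - kc / len(c))
                group_rows.append(OptoEffectRow(
                    area, epoch, task, tt, diff, (float(lo), float(hi)),
                    p, np.nan, len(c), len(s), testable=True))
            m = sum(r.testable for r in group_rows)
            for r in group_rows:
                if r.testable:
                    r.fisher_p_bonferroni = min(1.0, r.fisher_p * m)
            rows.extend(group_rows)

            sil_t = sil_ae[sil_ae["task"] == task]
            con_t = control[control["task"] == task]
            perf_rows.append(dict(
                area=area, epoch=epoch, task=task,
                performance_silenced=_performance(sil_t),
                performance_control=_performance(con_t),
            ))
    perf = pd.DataFrame(perf_rows)
    if not perf.empty:
        perf["performance_diff"] = (
            perf["performance_silenced"] - perf["performance_control"]
        )
    return rows, perf


def _performance(df: pd.DataFrame) -> float:
    """100 - FA rate(%) - miss rate(%)."""
    nogo = df[df["trial_type"].isin(["cue", "probe"])]
    go = df[df["trial_type"] == "target"]
    fa = 100.0 * (nogo["outcome"] == "FA").mean() if len(nogo) else 0.0
    miss = 100.0 * (go["outcome"] == "miss").mean() if len(go) else 0.0
    return 100.0 - fa - miss
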