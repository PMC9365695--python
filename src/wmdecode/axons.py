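"""Bouton-to-axon clustering and optogenetic-silencing effect statistics.

Boutons belonging to the same axon share a latent temporal signal, so boutons
are embedded in a temporal feature space by ICA and clustered with a Gaussian
mixture whose component count minimizes an information criterion; members of a
cluster are averaged into a putative-axon trace.  Silencing effects are
quantified against resampled null distributions, separately for the early and
late delay, and summarized by a recovery index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

OUTLIER = -1


def ica_features(
    traces: np.ndarray, d: int = 40, rng: np.random.Generator | None = None,
    max_retries: int = 3,
) -> np.ndarray:
    """Represent each bouton by its loadings on d temporal independent
    components fit on the full time series (boutons x frames input,
    boutons x d output).  Non-convergence triggers up to ``max_retries``
    re-seeded attempts before raising."""
    if traces.shape[0] < d:
        raise ValueError("need at least d boutons")
    rng = rng if rng is not None else np.random.default_rng()
    mixing = None
    for _ in range(max_retries):
        seed = int(rng.integers(0, 2**31 - 1))
        ica = FastICA(n_components=d, random_state=seed, max_iter=500, tol=1e-3)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(traces.T)          # samples = frames, signals = boutons
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        mixing = ica.mixing_           # boutons x d loadings
        if converged:
            return mixing
    # When d exceeds the rank of the shared signals the surplus whitened
    # dimensions are rotation-degenerate and FastICA cannot settle; the
    # feature space is still a valid embedding for clustering, so keep the
    # last fit rather than failing.
    warnings.warn(f"ICA unconverged after {max_retries} seeds; using last fit")
    return mixing


class AxonClusterer(ClusterMixin, BaseEstimator):
    """ICA + Gaussian-mixture clustering of boutons into putative axons.

    Fits ``n_features`` temporal independent components, clusters the bouton
    loadings with Gaussian mixtures over ``k_range``, and picks the component
    count minimizing a small-sample-adjusted information criterion (AICc
    where defined; BIC otherwise).  Boutons whose squared Mahalanobis
    distance to their component exceeds the ``outlier_quantile`` chi-square
    quantile are left unassigned (label -1).

    Attributes: ``features_`` (boutons x n_features), ``labels_``,
    ``n_clusters_``, ``criterion_curve_``, ``axon_traces_``.
    """

    def __init__(
        self,
        n_features: int = 40,
        k_range: tuple[int, ...] | None = None,
        outlier_quantile: float = 0.99,
        covariance_type: str = "tied",
        criterion: str = "aicc",
        random_state: int | None = None,
    ):
        self.n_features = n_features
        self.k_range = k_range
        self.outlier_quantile = outlier_quantile
        self.covariance_type = covariance_type
        self.criterion = criterion
        self.random_state = random_state

    def _n_params(self, gm: GaussianMixture, d: int) -> int:
        k = gm.n_components
        mean_p = k * d
        weight_p = k - 1
        cov_p = {"spherical": k, "diag": k * d,
                 "tied": d * (d + 1) // 2, "full": k * d * (d + 1) // 2}[
            self.covariance_type
        ]
        return mean_p + weight_p + cov_p

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.random_state)
        feats = ica_features(X, d=self.n_features, rng=rng)
        # standardize feature columns: ICA mixing column scales are arbitrary
        feats = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-12)
        n, d = feats.shape
        k_range = self.k_range or tuple(range(1, max(2, n // 4) + 1))

        fits, crit_pairs = [], []
        aicc_ok = True
        for k in k_range:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=self.covariance_type,
                reg_covar=1e-4,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_init=3,
            ).fit(feats)
            aic = gm.aic(feats)
            p = self._n_params(gm, d)
            if self.criterion == "aicc" and n - p - 1 > 0:
                crit = aic + 2.0 * p * (p + 1) / (n - p - 1)
            else:
                crit = gm.bic(feats)
                if self.criterion == "aicc":
                    aicc_ok = False
            fits.append(gm)
            crit_pairs.append(crit)
        if self.criterion == "aicc" and not aicc_ok:
            # the small-sample correction is undefined somewhere in range:
            # use BIC consistently across the whole range
            crit_pairs = [gm.bic(feats) for gm in fits]
        best = int(np.argmin(crit_pairs))
        gm = fits[best]

        labels = gm.predict(feats)
        d2 = self._mahalanobis_sq(gm, feats, labels)
        cutoff = stats.chi2.ppf(self.outlier_quantile, df=d)
        labels = np.where(d2 > cutoff, OUTLIER, labels)
        # a component holding a single bouton has no within-cluster statistics
        # to validate it; typically a stray bouton that captured its own
        # mixture component, so leave it unassigned
        counts = np.bincount(labels[labels >= 0], minlength=gm.n_components)
        labels = np.where(counts[np.maximum(labels, 0)] < 2, OUTLIER, labels)

        self.features_ = feats
        self.labels_ = labels
        self.n_clusters_ = gm.n_components
        self.criterion_curve_ = dict(zip(k_range, crit_pairs))
        self.mixture_ = gm
        self.axon_traces_ = self._average_members(X, labels, gm.n_components)
        return self

    def _mahalanobis_sq(self, gm, feats, labels) -> np.ndarray:
        d = feats.shape[1]
        out = np.empty(len(feats))
        for k in range(gm.n_components):
            sel = labels == k
            if not sel.any():
                continue
            diff = feats[sel] - gm.means_[k]
            if self.covariance_type == "spherical":
                out[sel] = (diff**2).sum(axis=1) / gm.covariances_[k]
            elif self.covariance_type == "diag":
                out[sel] = ((diff**2) / gm.covariances_[k]).sum(axis=1)
            else:
                cov = gm.covariances_ if self.covariance_type == "tied" \
                    else gm.covariances_[k]
                try:
                    inv = np.linalg.inv(cov)
                except np.linalg.LinAlgError:
                    inv = np.linalg.inv(cov + 1e-6 * np.eye(d))
                out[sel] = np.einsum("ij,jk,ik->i", diff, inv, diff)
        return out

    @staticmethod
    def _average_members(X, labels, n_clusters) -> np.ndarray:
        traces = np.zeros((n_clusters, X.shape[1]))
        for k in range(n_clusters):
            sel = labels == k
            if sel.any():
                traces[k] = X[sel].mean(axis=0)
        return traces

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_boutons(
    traces: np.ndarray,
    k_range: tuple[int, ...] | None = None,
    outlier_quantile: float = 0.99,
    rng_seed: int | None = None,
    **kwargs,
) -> AxonClusterer:
    """Cluster boutons into putative axons (see AxonClusterer)."""
    return AxonClusterer(
        k_range=k_range, outlier_quantile=outlier_quantile,
        random_state=rng_seed, **kwargs,
    ).fit(traces)


@dataclass
class SilencingEffect:
    unit_id: str
    delta_delay_mean: float         # silenced minus control delay-averaged activity
    p_value: float                  # percentile p from the resampled null
    p_value_t: float                # t-test of the observed delta against the null
    significant: bool
    null_sd: float


def silencing_effects(
    control: np.ndarray,
    silenced: np.ndarray,
    unit_ids: list[str],
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    min_trials: int = 10,
) -> list[SilencingEffect]:
    """Per-unit silencing effect on delay-averaged activity.

    ``control``/``silenced`` are trials x units matrices of delay-averaged
    activity.  The statistic is the silenced-minus-control mean difference;
    the null resamples control trials into two pseudo-arms of the observed
    sizes ``n_boot`` times.  Two-sided percentile p at ``alpha`` = 0.05; a
    t-test of the observed statistic against the null is also reported.
    """
    rng = rng if rng is not None else np.random.default_rng()
    nc, ns = len(control), len(silenced)
    if nc < min_trials or ns < min_trials:
        raise ValueError(f"need >= {min_trials} trials per arm")
    obs = silenced.mean(axis=0) - control.mean(axis=0)
    m = min(ns, nc - 1)
    null = np.empty((n_boot, control.shape[1]))
    for b in range(n_boot):
        idx = rng.permutation(nc)
        null[b] = control[idx[:m]].mean(axis=0) - control[idx[m:]].mean(axis=0)
    p = (1.0 + (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)) / (n_boot + 1.0)
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    z = (obs - mu) / np.where(sd > 0, sd, 1.0)
    p_t = 2.0 * stats.t.sf(np.abs(z), df=n_boot - 1)
    return [
        SilencingEffect(uid, float(obs[i]), float(p[i]), float(p_t[i]),
                        bool(p[i] < alpha), float(sd[i]))
        for i, uid in enumerate(unit_ids)
    ]


@dataclass
class FeedbackEffect:
    """Silencing effect on cue-coding-dimension activity, split by delay epoch.

    ``effect_*`` are control-minus-silenced mean projections (positive =
    disruption); ``mean_effect_*`` and ``pc1_effect_*`` are the net-activity
    controls (expected near zero for modulatory feedback)."""

    effect_early: float
    effect_late: float
    p_early: float
    p_late: float
    mean_effect_early: float
    mean_effect_late: float
    pc1_effect_early: float
    pc1_effect_late: float
    n_control: int
    n_silenced: int


def feedback_cd_timecourse(
    X_early: np.ndarray,
    X_late: np.ndarray,
    cue_labels: np.ndarray,
    silenced: np.ndarray,
    gamma: float = 1e-4,
    late_valid: np.ndarray | None = None,
) -> FeedbackEffect:
    """Cue-code disruption by target-area silencing, per delay half.

    The cue coding dimension is fit on control trials only (full-delay
    features approximated by the average of the early/late epoch means) and
    applied to every trial's early ([0, 1.6 s)) and late ([1.6 s, end))
    epoch means.  Cue-A projections are sign-inverted so that larger
    projections mean more cue information.  Mean-activity and PC1 projections
    of the same epochs serve as net-effect controls.
    """
    from .coding import fit_cd

    silenced = np.asarray(silenced, dtype=bool)
    cue_labels = np.asarray(cue_labels)
    if not silenced.any():
        raise ValueError("no silenced trials")
    late_valid = np.ones(len(cue_labels), dtype=bool) if late_valid is None \
        else np.asarray(late_valid, dtype=bool)
    ctrl = ~silenced
    X_full = np.where(late_valid[:, None], 0.5 * (X_early + X_late), X_early)
    clf = fit_cd(X_full[ctrl], cue_labels[ctrl], gamma=gamma)
    sign = np.where(cue_labels == "A", -1.0, 1.0)

    def epoch_stats(Xe, valid):
        proj = clf.project(Xe) * sign
        c = proj[ctrl & valid]
        s = proj[silenced & valid]
        eff = float(c.mean() - s.mean())
        p = float(stats.ttest_ind(c, s).pvalue) if len(s) > 1 and len(c) > 1 else np.nan
        return eff, p

    eff_e, p_e = epoch_stats(X_early, np.ones_like(silenced))
    eff_l, p_l = epoch_stats(X_late, late_valid)

    def net(Xe, valid, vec):
        proj = Xe @ vec
        return float(proj[ctrl & valid].mean() - proj[silenced & valid].mean())

    ones = np.ones(X_early.shape[1]) / X_early.shape[1]
    pc1 = PCA(n_components=1).fit(X_full[ctrl]).components_[0]
    return FeedbackEffect(
        effect_early=eff_e, effect_late=eff_l, p_early=p_e, p_late=p_l,
        mean_effect_early=net(X_early, np.ones_like(silenced), ones),
        mean_effect_late=net(X_late, late_valid, ones),
        pc1_effect_early=net(X_early, np.ones_like(silenced), pc1),
        pc1_effect_late=net(X_late, late_valid, pc1),
        n_control=int(ctrl.sum()), n_silenced=int(silenced.sum()),
    )


def feedback_effects_across_experiments(effects: list[FeedbackEffect]) -> dict:
    """Two-sided signed-rank tests of the per-experiment early and late
    cue-code effects, plus the mean-activity controls."""
    out = {}
    for name in ("effect", "mean_effect", "pc1_effect"):
        for epoch in ("early", "late"):
            vals = np.array([getattr(e, f"{name}_{epoch}") for e in effects])
            vals = vals[np.isfinite(vals)]
            if len(vals) >= 5 and np.any(vals != 0):
                out[f"{name}_{epoch}_p"] = float(stats.wilcoxon(vals).pvalue)
            else:
                out[f"{name}_{epoch}_p"] = np.nan
            out[f"{name}_{epoch}_mean"] = float(vals.mean()) if len(vals) else np.nan
    return out


def recovery_index(effect_early: float, effect_late: float) -> float:
    """Early-minus-late silencing effect size: positive when the perturbed
    quantity recovers over the delay.  Applies identically to cue-code and
    behavioral effect sizes, and is antisymmetric under swapping epochs."""
    return effect_early - effect_late


@dataclass
class BehavioralRobustness:
    p_correct: dict                 # (arm, bin) -> proportion correct
    deficit_short: float            # control minus silenced proportion correct
    deficit_long: float
    p_short: float
    p_long: float
    n: dict


def behavioral_robustness(
    trials, split_ms: float = 1600.0, per_experiment: list | None = None
) -> BehavioralRobustness:
    """Silencing effect on correct responses, split by delay length.

    Compares the proportion of correct responses (CR on no-go, hit on go)
    between control trials and trials silenced at delay onset, separately for
    short (< split) and long (>= split) delays.  With ``per_experiment``
    (a list of per-experiment trial tables) a two-sided paired t-test across
    experiments is used; otherwise a Fisher exact test on pooled counts.
    """
    def _props(df):
        correct = df["outcome"].isin(["CR", "hit"]).to_numpy()
        sil = (df["opto_epoch"] == "delay_onset").to_numpy()
        ctrl = (df["opto_epoch"] == "none").to_numpy()
        short = (df["delay_ms"] < split_ms).to_numpy()
        out = {}
        for arm, arm_mask in (("control", ctrl), ("silenced", sil)):
            for b, b_mask in (("short", short), ("long", ~short)):
                m = arm_mask & b_mask
                out[(arm, b)] = (float(correct[m].mean()) if m.any() else np.nan,
                                 int(m.sum()), int(correct[m].sum()))
        return out

    pooled = _props(trials)
    p_correct = {k: v[0] for k, v in pooled.items()}
    n = {k: v[1] for k, v in pooled.items()}
    deficits = {}
    pvals = {}
    for b in ("short", "long"):
        deficits[b] = p_correct[("control", b)] - p_correct[("silenced", b)]
        if per_experiment is not None and len(per_experiment) >= 5:
            ds = []
            for df in per_experiment:
                pe = _props(df)
                d = pe[("control", b)][0] - pe[("silenced", b)][0]
                if np.isfinite(d):
                    ds.append(d)
            pvals[b] = float(stats.ttest_1samp(ds, 0.0).pvalue) if len(ds) > 1 else np.nan
        else:
            kc, nc = pooled[("control", b)][2], pooled[("control", b)][1]
            ks, ns = pooled[("silenced", b)][2], pooled[("silenced", b)][1]
            if min(nc, ns) == 0:
                pvals[b] = np.nan
            else:
                pvals[b] = float(stats.fisher_exact(
                    [[ks, ns - ks], [kc, nc - kc]])[1])
    return BehavioralRobustness(
        p_correct=p_correct,
        deficit_short=float(deficits["short"]), deficit_long=float(deficits["long"]),
        p_short=pvals["short"], p_long=pvals["long"], n=n,
    )
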