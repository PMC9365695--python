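import numpy as np
import pytest
from scipy import integrate

import wmdecode as wd


RNG_SEED = 99


class TestDelaySampler:
    def test_support_bounds(self):
        rng = np.random.default_rng(RNG_SEED)
        d = wd.sample_delays(200_000, wd.TaskParams(), rng)
        assert d.min() >= 800.0
        assert d.max() <= 4000.0

    def test_mean_matches_closed_form(self):
        tp = wd.TaskParams()
        rng = np.random.default_rng(RNG_SEED)
        d = wd.sample_delays(1_000_000, tp, rng)
        expect = 1600.0 - 1000.0 * np.exp(-4.0)
        assert wd.expected_delay_mean_ms(tp) == pytest.approx(expect, abs=1e-9)
        assert d.mean() == pytest.approx(expect, abs=3.0)

    def test_moments_match_numerical_integration_oracle(self):
        # density: shifted-exponential on [800, 4000] truncated at the cap,
        # plus a uniform lump on [3600, 4000] carrying the tail mass exp(-4)
        lam = 1.0 / 800.0
        p_over = np.exp(-4.0)

        def trunc_moment(k):
            val, _ = integrate.quad(
                lambda x: x**k * lam * np.exp(-lam * (x - 800.0)), 800.0, 4000.0
            )
            return val

        def lump_moment(k):
            return p_over * (4000.0 ** (k + 1) - 3600.0 ** (k + 1)) / (400.0 * (k + 1))

        m1 = trunc_moment(1) + lump_moment(1)
        m2 = trunc_moment(2) + lump_moment(2)
        var = m2 - m1**2
        rng = np.random.default_rng(RNG_SEED)
        d = wd.sample_delays(1_000_000, wd.TaskParams(), rng)
        assert d.mean() == pytest.approx(m1, abs=3.0)
        assert d.var() == pytest.approx(var, rel=0.01)

    def test_resample_fraction_is_exponential_tail(self):
        rng = np.random.default_rng(RNG_SEED)
        d = wd.sample_delays(1_000_000, wd.TaskParams(), rng)
        frac = (d >= 3600.0).mean() - np.exp(-3.5) + np.exp(-4.0)
        # P(in [3600, 4000]) = natural mass exp(-3.5)-exp(-4) + resampled exp(-4)
        assert frac == pytest.approx(np.exp(-4.0), abs=1e-3)


class TestTrialGenerator:
    @pytest.fixture(scope="class")
    def big_session(self):
        rng = np.random.default_rng(RNG_SEED)
        return wd.generate_trials(200_000, wd.TaskParams(), rng)

    def test_mandatory_cue_after_probe_or_target(self, big_session):
        tt = big_session.trials["trial_type"].to_numpy()
        after = tt[1:][np.isin(tt[:-1], ["probe", "target"])]
        assert (after == "cue").all()

    def test_conditional_target_probability(self, big_session):
        tt = big_session.trials["trial_type"].to_numpy()
        nxt = tt[1:][tt[:-1] == "cue"]
        assert (nxt == "target").mean() == pytest.approx(0.10, abs=0.004)

    def test_stationary_target_frequency(self, big_session):
        # stationary distribution of the 3-state chain: cue 10/12, others 1/12
        tt = big_session.trials["trial_type"].to_numpy()
        assert (tt == "target").mean() == pytest.approx(1 / 12, abs=0.002)
        assert (tt == "probe").mean() == pytest.approx(1 / 12, abs=0.002)

    def test_empirical_transition_matrix(self, big_session):
        tt = big_session.trials["trial_type"].to_numpy()
        kinds = ["cue", "probe", "target"]
        expect = np.array([[0.8, 0.1, 0.1], [1, 0, 0], [1, 0, 0]])
        T = np.zeros((3, 3))
        for i, a in enumerate(kinds):
            sel = tt[:-1] == a
            for j, b in enumerate(kinds):
                T[i, j] = (tt[1:][sel] == b).mean()
        assert np.abs(T - expect).max() < 0.005

    def test_wm_cue_mirrors_target_and_switches_after_target(self):
        rng = np.random.default_rng(RNG_SEED)
        s = wd.generate_trials(5000, wd.TaskParams(), rng,
                               task_schedule=[("WM", "NONE", 5000)])
        df = s.trials
        cur = None
        for row in df.itertuples(index=False):
            if row.trial_type == "cue":
                if cur is not None:
                    assert row.stimulus_orientation == -cur
                cur = -row.stimulus_orientation
            elif row.trial_type == "target":
                assert row.stimulus_orientation == cur
                cur = -cur

    def test_seeded_generation_is_bit_reproducible(self):
        a = wd.generate_trials(500, wd.TaskParams(), np.random.default_rng(7))
        b = wd.generate_trials(500, wd.TaskParams(), np.random.default_rng(7))
        assert a.trials.equals(b.trials)


class TestResponses:
    def _fa_slope(self, fa_slope, n=60_000, seed=RNG_SEED):
        rng = np.random.default_rng(seed)
        s = wd.generate_trials(n, wd.TaskParams(halt_rate=0, early_lick_rate=0,
                                                opto_fraction=0), rng,
                               task_schedule=[("WM", "CW", n)])
        bp = wd.BehaviorParams(fa_slope_per_s=fa_slope)
        s = wd.simulate_responses(s, bp, rng)
        cues = s.trials[s.trials.trial_type == "cue"]
        return wd.response_curve(cues).slope_pct_per_s

    def test_fa_slope_recovered(self):
        assert self._fa_slope(0.119) == pytest.approx(11.9, abs=1.0)

    def test_zero_slope_null(self):
        assert self._fa_slope(0.0) == pytest.approx(0.0, abs=0.5)

    def test_probe_responses_delay_independent(self):
        rng = np.random.default_rng(RNG_SEED)
        n = 120_000
        s = wd.generate_trials(n, wd.TaskParams(halt_rate=0, early_lick_rate=0,
                                                opto_fraction=0), rng,
                               task_schedule=[("WM", "CW", n)])
        s = wd.simulate_responses(s, wd.BehaviorParams(fa_slope_per_s=0.119), rng)
        probes = s.trials[s.trials.trial_type == "probe"]
        assert wd.response_curve(probes).slope_pct_per_s == pytest.approx(0.0, abs=1.0)

    def test_responses_reproducible(self):
        tp = wd.TaskParams()
        s = wd.generate_trials(300, tp, np.random.default_rng(5))
        a = wd.simulate_responses(s, wd.BehaviorParams(), np.random.default_rng(6))
        b = wd.simulate_responses(s, wd.BehaviorParams(), np.random.default_rng(6))
        assert a.trials.equals(b.trials)


class TestPopulation:
    def test_no_code_means_chance_decoding(self):
        rng = np.random.default_rng(RNG_SEED)
        tp = wd.TaskParams(halt_rate=0, early_lick_rate=0, opto_fraction=0)
        s = wd.generate_trials(420, tp, rng)
        np_ = wd.NeuralParams(n_cells=60, code_amplitude=0.0)
        store, _ = wd.simulate_population(s, np_, rng)
        f = wd.filter_trials(s, imaging=True)
        from wmdecode.pipelines import delay_features
        feats = delay_features(f, store, include_stim_frames=False)
        res = wd.loo_decode(feats.X[feats.ok], feats.task[feats.ok])
        assert res.accuracy == pytest.approx(0.5, abs=0.06)

    def test_bumps_only_is_low_rank(self):
        rng = np.random.default_rng(RNG_SEED)
        tp = wd.TaskParams(halt_rate=0, early_lick_rate=0, opto_fraction=0)
        s = wd.generate_trials(300, tp, rng)
        np_ = wd.NeuralParams(n_cells=60, n_seq_bumps=3, code_amplitude=0.0,
                              stim_amplitude=0.0, stim_code_amplitude=0.0,
                              noise_sigma=0.02)
        store, _ = wd.simulate_population(s, np_, rng)
        f = wd.filter_trials(s, imaging=True)
        from wmdecode import geometry as geo
        ea = geo.prepare_experiment(f, store, stim_window_ms=0.0)
        M = np.nan_to_num(np.nanmean(ea.delay_tensor, axis=0))
        pca = geo.fit_pcs(M)
        assert pca.explained_variance_ratio_[:3].sum() >= 0.75

    def test_decoding_monotone_in_code_amplitude(self):
        # planted-code recovery: accuracy non-decreasing in expectation
        from wmdecode.pipelines import delay_features
        amps = [0.0, 0.05, 0.1, 0.2, 0.4]
        acc = []
        for amp in amps:
            reps = []
            for r in range(3):
                rng = np.random.default_rng(1000 + r)
                tp = wd.TaskParams(halt_rate=0, early_lick_rate=0, opto_fraction=0)
                s = wd.generate_trials(260, tp, rng)
                np_ = wd.NeuralParams(n_cells=50, code_amplitude=amp)
                store, _ = wd.simulate_population(s, np_, rng)
                f = wd.filter_trials(s, imaging=True)
                feats = delay_features(f, store, include_stim_frames=False)
                reps.append(wd.loo_decode(feats.X[feats.ok],
                                          feats.task[feats.ok]).accuracy)
            acc.append(np.mean(reps))
        assert acc[0] == pytest.approx(0.5, abs=0.08)
        # allow small MC wiggle while requiring an overall increasing trend
        assert all(b >= a - 0.05 for a, b in zip(acc, acc[1:]))
        assert acc[-1] > acc[0] + 0.15

    def test_population_reproducible(self):
        tp = wd.TaskParams()
        s = wd.generate_trials(60, tp, np.random.default_rng(3))
        a, _ = wd.simulate_population(s, wd.NeuralParams(n_cells=20),
                                      np.random.default_rng(4))
        b, _ = wd.simulate_population(s, wd.NeuralParams(n_cells=20),
                                      np.random.default_rng(4))
        np.testing.assert_array_equal(a.activity, b.activity)


class TestBoutons:
    def test_mean_boutons_per_axon(self):
        rng = np.random.default_rng(RNG_SEED)
        tp = wd.TaskParams(halt_rate=0, early_lick_rate=0)
        s = wd.generate_trials(20, tp, rng, task_schedule=[("WM", "CW", 20)])
        ap = wd.AxonParams(n_axons=200)
        _, labels, _, _ = wd.simulate_boutons(s, ap, rng=rng)
        counts = np.bincount(labels, minlength=200)
        assert counts.mean() == pytest.approx(8.0, abs=0.5)
        assert counts.min() >= 1

    def test_noiseless_boutons_are_identical_copies(self):
        rng = np.random.default_rng(RNG_SEED)
        tp = wd.TaskParams(halt_rate=0, early_lick_rate=0)
        s = wd.generate_trials(15, tp, rng, task_schedule=[("WM", "CW", 15)])
        ap = wd.AxonParams(n_axons=10, bouton_noise_sigma=0.0)
        bst, labels, ast, _ = wd.simulate_boutons(s, ap, rng=rng)
        for k in range(10):
            rowsk = bst.activity[labels == k]
            assert np.allclose(rowsk, rowsk[0])
            np.testing.assert_allclose(rowsk[0], ast.activity[k])

    def test_full_attenuation_removes_cue_code(self):
        rng = np.random.default_rng(RNG_SEED)
        tp = wd.TaskParams(halt_rate=0, early_lick_rate=0, opto_fraction=0.5,
                           opto_epochs=("delay_onset",))
        s = wd.generate_trials(600, tp, rng, task_schedule=[("WM", "CW", 600)])
        from dataclasses import replace
        np_ = replace(wd.NeuralParams(), n_cells=30, frame_rate_hz=22.78,
                      noise_sigma=0.0, rectify=False, task_code_scale=0.0,
                      bump_amplitude=0.0, baseline=0.0)
        ap = wd.AxonParams(n_axons=30, bouton_noise_sigma=0.0,
                           silencing_cue_attenuation=1.0,
                           silencing_recovery_ms=None)
        _, _, ast, truth = wd.simulate_boutons(s, ap, np_, rng)
        from wmdecode.pipelines import delay_features
        f = wd.filter_trials(s, imaging=True)
        feats = delay_features(f, ast, include_stim_frames=False)
        m = feats.wm_cue_mask
        proj = feats.X[m] @ truth.cue_code
        sil = feats.silenced_delay_onset[m]
        assert np.abs(proj[sil]).max() < 1e-9
        assert np.abs(proj[~sil]).mean() > 0.05
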