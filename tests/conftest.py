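import numpy as np
import pandas as pd
import pytest

import wmdecode as wd


def make_trials(rows):
    """Build a valid trial table from a list of per-trial overrides."""
    base = dict(
        task="WM", rotation="CW", trial_type="cue", cue_identity="A",
        prev_cue_identity="A", stimulus_orientation=-45.0, delay_ms=1500.0,
        stimulus_ms=2000.0, lick_latency_ms=np.nan, outcome="CR",
        opto_epoch="none", opto_area="NA", halted=False, early_lick=False,
    )
    out = []
    onset = 0.0
    for i, row in enumerate(rows):
        d = dict(base, trial_index=i, delay_onset_ms=onset)
        d.update(row)
        out.append(d)
        onset = d["delay_onset_ms"] + d["delay_ms"] + d["stimulus_ms"]
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def behavior_session():
    """A mid-sized simulated session with outcomes, both tasks and rotations."""
    rng = np.random.default_rng(101)
    tp = wd.TaskParams(halt_rate=0.0, early_lick_rate=0.0, opto_fraction=0.0)
    s = wd.generate_trials(4000, tp, rng)
    return wd.simulate_responses(s, wd.BehaviorParams(), rng)


@pytest.fixture(scope="session")
def imaging_session():
    """A small imaging-style session with a simulated population."""
    rng = np.random.default_rng(202)
    tp = wd.TaskParams(halt_rate=0.0, early_lick_rate=0.0, opto_fraction=0.0)
    s = wd.generate_trials(400, tp, rng)
    s = wd.simulate_responses(s, wd.BehaviorParams(), rng)
    np_ = wd.NeuralParams(n_cells=80)
    store, truth = wd.simulate_population(s, np_, rng)
    return s, store, truth
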