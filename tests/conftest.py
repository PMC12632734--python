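import numpy as np
import pandas as pd
import pytest

from wmstates import EpochSpec, SimConfig, SpikeDataset, TuningSpec, simulate_tuned_session


def make_dataset(spikes_by_unit_trial, n_trials=2, locations=None, areas=None):
    """Small hand-built dataset. ``spikes_by_unit_trial``: {(unit, trial): [times]}."""
    units = sorted({u for u, _ in spikes_by_unit_trial})
    rows = [
        (u, t, s)
        for (u, t), times in spikes_by_unit_trial.items()
        for s in times
    ]
    spikes = pd.DataFrame(rows, columns=["unit_id", "trial_id", "time_s"])
    locations = locations if locations is not None else [0.0] * n_trials
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "cue_location_deg": locations,
            "correct": True,
            "rt_ms": np.nan,
        }
    )
    areas = areas or {u: "PFC" for u in units}
    units_df = pd.DataFrame(
        {
            "unit_id": units,
            "area": [areas[u] for u in units],
            "depth_mm": 0.5,
            "kind": "single",
        }
    )
    return SpikeDataset(spikes, trials, units_df, EpochSpec()).validate()


@pytest.fixture(scope="session")
def untuned_session():
    """A flat-rate (gain 1) session: no location information anywhere."""
    cfg = SimConfig(
        n_neurons=30, n_trials_per_location=20, tuning=TuningSpec(kappa=2.0, gain=1.0), seed=101
    )
    return simulate_tuned_session(cfg)


@pytest.fixture(scope="session")
def tuned_session():
    """A strongly tuned mid-size session used across decoding/PEV tests."""
    cfg = SimConfig(
        n_neurons=40, n_trials_per_location=10, tuning=TuningSpec(kappa=2.0, gain=5.0), seed=77
    )
    return simulate_tuned_session(cfg)
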