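import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dockfret as df
from dockfret.idealize import Dwell

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def sidecar_dwell_lists(sidecars, frame_interval=0.06):
    """Ground-truth dwell lists (one per dynamic molecule) from sidecars."""
    out = []
    for s in sidecars:
        if s.static or len(s.dwell_states) < 2:
            continue
        out.append([
            Dwell(state=int(st), n_frames=max(int(round(du / frame_interval)), 1),
                  duration=float(du), left_censored=(i == 0),
                  right_censored=(i == len(s.dwell_states) - 1),
                  mean_fret=0.0, molecule_id=s.molecule_id)
            for i, (st, du) in enumerate(zip(s.dwell_states, s.dwell_durations))
        ])
    return out


def two_level_trace(state_path, frame_interval=0.06, mu=(0.5, 0.95), i_total=500.0,
                    molecule_id="mol"):
    """Noiseless frame-aligned two-level intensity trace from a 0/1 path."""
    path = np.asarray(state_path, dtype=int)
    eff = np.where(path == 1, mu[1], mu[0])
    return df.IntensityTrace((1.0 - eff) * i_total, eff * i_total, frame_interval,
                             molecule_id=molecule_id)


@pytest.fixture(scope="session")
def small_dataset():
    """20 simulated molecules at the default (no-osmolyte) condition."""
    cfg = df.SimulationConfig(rng_seed=11)
    return df.simulate_condition_dataset(cfg, 20)


@pytest.fixture(scope="session")
def accepted_traces(small_dataset):
    dataset, _ = small_dataset
    accepted, _ = df.select_traces(dataset)
    return accepted
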