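"""Shared fixtures: tiny hand-built sessions and spike tables.

Everything here is generated programmatically; the expensive shared
benchmark run lives in test_acceptance.py as a module-scoped fixture.
"""

import numpy as np
import pandas as pd
import pytest

from hippomimo import (
    GLVMCoefficients,
    MIMOConfig,
    SpikeTrainSet,
    simulate_output,
)
from hippomimo.spike_data import ConcatenatedSession


@pytest.fixture
def tiny_spike_set() -> SpikeTrainSet:
    """Two CA3 + one CA1 neurons, three trials, one sample event each."""
    spikes = pd.DataFrame(
        {
            "trial_id": [0, 0, 0, 1, 1, 2, 2, 2],
            "neuron_id": ["c3a", "c3a", "c3b", "c3a", "ca1x", "c3b", "ca1x", "ca1x"],
            "region": ["CA3", "CA3", "CA3", "CA3", "CA1", "CA3", "CA1", "CA1"],
            "spike_time_s": [1.5, 2.0, 2.5, 9.5, 10.1, 17.9, 18.0, 18.6],
        }
    )
    events = pd.DataFrame(
        {
            "trial_id": [0, 1, 2],
            "event_code": ["LS", "RS", "LS"],
            "event_time_s": [2.0, 10.0, 18.0],
        }
    )
    neurons = pd.DataFrame(
        {"neuron_id": ["c3a", "c3b", "ca1x"], "region": ["CA3", "CA3", "CA1"]}
    )
    return SpikeTrainSet(neurons=neurons, spikes=spikes, events=events)


def make_toy_session(
    n_inputs=2,
    n_segments=8,
    segment_bins=400,
    rate_per_bin=0.05,
    seed=0,
    truth: GLVMCoefficients | None = None,
    config: MIMOConfig | None = None,
):
    """Small concatenated session with output simulated from known truth.

    Uses a short 100-bin memory (pole 0.9) so design building and
    fitting stay fast in unit tests.
    """
    cfg = config or MIMOConfig(
        J=2, L=2, alpha_ff=0.9, alpha_fb=0.9, memory_ff_bins=100, memory_fb_bins=100
    )
    rng = np.random.default_rng(seed)
    ff, fb = cfg.make_bases()
    T = n_segments * segment_bins
    inputs = (rng.random((n_inputs, T)) < rate_per_bin).astype(np.int8)
    if truth is None:
        n_pair = cfg.J * (cfg.J + 1) // 2
        c1 = rng.normal(0, 0.5, (n_inputs, cfg.J))
        c2s = rng.normal(0, 0.05, (n_inputs, n_pair))
        truth = GLVMCoefficients(
            c0=-1.6, c1=c1, c2s=c2s, ch=np.array([-1.0, 0.3])[: cfg.L]
        )
    session = ConcatenatedSession(
        inputs=inputs,
        outputs=np.zeros((1, T), dtype=np.int8),
        segment_bounds=[i * segment_bins for i in range(n_segments)],
        input_ids=[f"in{i}" for i in range(n_inputs)],
        output_ids=["out0"],
    )
    Y, _ = simulate_output(truth, session, ff, fb, 1, seed=seed + 1)
    session.outputs = Y
    return session, truth, cfg, ff, fb
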