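import sys
from pathlib import Path

import pytest

# make tests/reference.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))


# Study conditions for the steady-state acceptance checks: the full
# 10,000-neuron candidate network run for 400 s with the 1 Hz background
# variant; the raster is retained from 60 s on.  Shared session-wide
# because the run dominates the suite's cost.
STEADY = dict(
    n_neurons=10_000,
    duration_s=400.0,
    seed=1,
    background_rate_hz=1.0,
    raster_window_s=(60.0, 400.0),
    chunk_steps=5000,
)


@pytest.fixture(scope="session")
def steady_run():
    from critnet.simulator import SimulationConfig, run

    return run(SimulationConfig(**STEADY))
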