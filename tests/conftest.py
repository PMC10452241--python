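import numpy as np
import pytest

import multifq as m


@pytest.fixture(scope="session")
def waveclus_cfg():
    return m.get_profile("waveclus25k", K=3, seed=0)


@pytest.fixture(scope="session")
def hc_cfg():
    return m.get_profile("hc10k", K=3, seed=0)


@pytest.fixture(scope="session")
def templates3():
    """Three screened unit templates at the 25 kHz benchmark geometry."""
    return m.make_templates(3, 64, 25_000.0, similarity=0.3, seed=1)


@pytest.fixture(scope="session")
def small_dataset(templates3):
    """A short ground-truthed recording at low noise (fast to sort)."""
    spec = m.SimulationSpec(
        templates=templates3, duration_s=10.0, noise_std=0.05, seed=1
    )
    return m.simulate(spec)


@pytest.fixture(scope="session")
def sorted_small(small_dataset, waveclus_cfg):
    return m.run_pipeline(small_dataset.recording, waveclus_cfg, small_dataset.truth)


def single_spike_recording(template: np.ndarray, rate_hz: float, n: int = 5000,
                           peak_at: int = 2500) -> m.RawRecording:
    """Noise-free trace with one template inserted, its extremum at peak_at."""
    x = np.zeros(n)
    off = int(np.argmax(np.abs(template)))
    x[peak_at - off : peak_at - off + template.size] += template
    return m.RawRecording(samples=x, rate_hz=rate_hz)
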