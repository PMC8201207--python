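import numpy as np
import pytest

import thermoroi as tr


@pytest.fixture(scope="session")
def noiseless_sweep():
    """Deterministic full-size sweep without noise, drift or interferences."""
    spec = tr.PhantomSpec(seed=11, noise_sd_c=0.0, render_visible=False)
    captures, truth = tr.generate_sweep(spec)
    return spec, captures, truth


@pytest.fixture(scope="session")
def study_sweep():
    """Sweep at the study's acquisition conditions (sensor noise, visibles)."""
    spec = tr.PhantomSpec(seed=7)
    captures, truth = tr.generate_sweep(spec)
    return spec, captures, truth


@pytest.fixture()
def small_frame():
    values = np.full((6, 8), 22.0)
    values[2:5, 3:6] = 34.0
    return tr.TemperatureFrame(values=values, frame_id="toy")
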