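import warnings

import numpy as np
import pytest

from nociscreen.synthgen import CompoundTruth, PlateSpec, simulate_plate

# the literal 10 kHz band edge always clips at 20 kHz sampling; the
# warning is expected and would otherwise drown real ones in test output
warnings.filterwarnings("ignore", message="band_high .* Nyquist")


@pytest.fixture
def small_spec():
    """A few channels at full 20 kHz over a short window: trace-level
    behaviour without full-plate cost."""
    return PlateSpec(n_wells=2, n_electrodes_per_well=6, duration=30.0,
                     active_fraction=1.0, seed=11)


@pytest.fixture
def suppressor_truth():
    return CompoundTruth("CMP", ic50_true=2.0, hill_n_true=3.0)


@pytest.fixture
def small_plate(small_spec):
    return simulate_plate(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
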