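import numpy as np
import pytest

from arto import (FitParameters, ProbeSignal, SimulationSpec, add_gaussian_noise,
                  simulate_clean_signal)


@pytest.fixture(scope="session")
def default_spec():
    return SimulationSpec()


@pytest.fixture(scope="session")
def small_spec():
    """Short chromosome used where full-size runs would be wasteful."""
    return SimulationSpec(n_probes=800)


@pytest.fixture(scope="session")
def clean_signal(default_spec):
    return simulate_clean_signal(default_spec, seed=20260921)


@pytest.fixture(scope="session")
def noisy_signal(default_spec, clean_signal):
    clean, truth = clean_signal
    return add_gaussian_noise(clean, 0.15, seed=7), truth


@pytest.fixture()
def flat_signal():
    """60 probes at a constant level (one CTR)."""
    pos = 40_000 * np.arange(1, 61)
    return ProbeSignal("chrT", pos, np.full(60, 1.5))


def make_v_signal(n_left=20, n_mid=20, n_right=20, slope=2.0e-6, level=1.8,
                  spacing=40_000):
    """CTR - descending TTR - CTR, exactly piecewise linear."""
    pos = spacing * np.arange(1, n_left + n_mid + n_right + 1)
    left = np.full(n_left, level)
    mid = level - slope * spacing * np.arange(1, n_mid + 1)
    right = np.full(n_right, mid[-1])
    return ProbeSignal("chrV", pos, np.concatenate([left, mid, right]))


@pytest.fixture()
def v_signal():
    return make_v_signal()
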