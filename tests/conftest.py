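import numpy as np
import pytest

from breathmod import coupling, spectral, synth


@pytest.fixture(scope="session")
def grid36():
    return spectral.frequency_grid()


@pytest.fixture(scope="session")
def breath_trace():
    """Five minutes of jittered synthetic breathing at 300 Hz."""
    return synth.gen_respiration(300.0, 300.0, 4.0, 0.5, seed=11)


@pytest.fixture(scope="session")
def breath_phase(breath_trace):
    return coupling.extract_phase(breath_trace)


def brute_force_peaks(x, min_gap=1):
    """O(n) scan for strict local maxima with a refractory gap: the
    independent oracle for peak-based checks."""
    x = np.asarray(x)
    peaks = []
    for i in range(1, x.size - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            if not peaks or i - peaks[-1] >= min_gap:
                peaks.append(i)
    return np.asarray(peaks, dtype=int)
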