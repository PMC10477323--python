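import numpy as np
import pytest

from lcpupil.core import GammaShape, SampledSeries


@pytest.fixture
def control_irf() -> GammaShape:
    """Wave-like response function: mean 600 ms, excess kurtosis 2.4."""
    return GammaShape(shape=2.5, scale=0.24, amplitude=1.0)


@pytest.fixture
def wave_input() -> GammaShape:
    """Control-like neural input: mean ~657 ms, excess kurtosis ~2.51."""
    return GammaShape(shape=2.388, scale=0.27487, amplitude=0.12, t0=0.0005)


@pytest.fixture
def impulse_input() -> GammaShape:
    """Impulse-like neural input: mean ~43 ms, excess kurtosis ~37.5."""
    return GammaShape(shape=0.16007, scale=0.26607, amplitude=0.12, t0=0.00041)


def constant_series(value: float, n: int, rate: float = 500.0) -> SampledSeries:
    return SampledSeries(np.full(n, value), rate)


@pytest.fixture
def noiseless_diff(control_irf, wave_input):
    """Noiseless convolution of a known input with a known IRF on a
    1000 Hz, 4 s grid."""
    rate = 1000.0
    t = np.arange(int(4 * rate)) / rate
    model = np.convolve(wave_input.density(t), control_irf.density(t))[: len(t)] / rate
    return SampledSeries(model, rate)
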