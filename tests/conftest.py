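import numpy as np
import pytest

from myofluor import BiExpParams, DecayHistogram, delta_irf, model_decay
from myofluor.decay import DEFAULT_N_BINS, DEFAULT_PERIOD_NS
from myofluor.simulate import simulate_irf

N_BINS = DEFAULT_N_BINS
PERIOD = DEFAULT_PERIOD_NS
BIN_WIDTH = PERIOD / N_BINS

#: Control-regime decay parameters of the NAD(P)H channel (CH2).
CONTROL_CH2 = dict(a1=0.87, a2=0.13, tau1=0.82, tau2=3.47)


@pytest.fixture(scope="session")
def gaussian_irf():
    return simulate_irf(0.25, n_bins=N_BINS, bin_width=BIN_WIDTH)


@pytest.fixture(scope="session")
def control_params():
    return BiExpParams(**CONTROL_CH2)


@pytest.fixture(scope="session")
def noiseless_control_hist(gaussian_irf):
    """Exact model evaluation at realistic scale, usable as a fit target."""
    params = BiExpParams(a1=8.7e5, a2=1.3e5, tau1=0.82, tau2=3.47)
    expected = model_decay(params, gaussian_irf, BIN_WIDTH, PERIOD)
    return DecayHistogram(expected, bin_width=BIN_WIDTH, period=PERIOD), params
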