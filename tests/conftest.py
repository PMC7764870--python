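import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import filmrheo as fr

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def single_exp_transient():
    """Noiseless 1-component transient: A=10, tau=100 s, no plateau."""
    return fr.gen_relaxation([(10.0, 100.0)], plateau=0.0, strain=0.05,
                             pi0=18.0, sampling=(1.0, 1000.0))


@pytest.fixture
def two_exp_transient():
    """Noiseless 2-component transient, tau = (10, 1000) s, plateau 2."""
    return fr.gen_relaxation([(5.0, 10.0), (5.0, 1000.0)], plateau=2.0,
                             strain=0.05, pi0=18.0, sampling=(1.0, 10000.0))


@pytest.fixture
def isotherm_pair():
    """Noiseless squeeze-out-like (reference, test) recording pair."""
    return fr.gen_isotherm_pair(**fr.isotherm_preset())


@pytest.fixture
def kinetics_trace():
    """Noiseless penetration trace: 15 mN/m amplitude, rise 20 s, decay 300 s."""
    return fr.gen_kinetics(**fr.kinetics_preset())


def squeeze_out_oracle(truth, threshold, n_dense=200_001):
    """Dense-grid evaluation of the generator's shift model.

    Returns the test-branch pressure at the first point (scanning toward
    smaller area) from which the shift stays below ``threshold``, or None.
    Reads only the truth sidecar, never the analysis under test.
    """
    from filmrheo.synthetic_data import base_isotherm_template, logistic_shift

    tmpl = base_isotherm_template(truth["waypoints"])
    area = np.linspace(tmpl.x[0], tmpl.x[-1], n_dense)
    pi_base = tmpl(area)
    shift = logistic_shift(pi_base, truth["shift_amplitude"],
                           truth["vanish_pressure"], truth["vanish_width"])
    shift = np.atleast_1d(shift)
    order = np.argsort(area)[::-1]  # compression: decreasing area
    shift_c = shift[order]
    pi_test_c = (pi_base + shift)[order]
    start = None
    for i in range(shift_c.size - 1, -1, -1):
        if shift_c[i] < threshold:
            start = i
        else:
            break
    return None if start is None else float(pi_test_c[start])
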