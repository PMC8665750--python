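import math

import numpy as np
import pytest

from peakline import EIC, ROI, PeakSpec, RunRecipe, simulate_run


@pytest.fixture
def gaussian_eic():
    """Noiseless gaussian EIC on a 1 s grid: A=1000, mu=50, sigma=4."""
    t = np.arange(0.0, 101.0)
    y = 1000.0 * np.exp(-0.5 * ((t - 50.0) / 4.0) ** 2)
    return EIC(sample_id="s", cpd_id="c", rt=t, intensity=y)


@pytest.fixture
def simple_roi():
    return ROI(cpd_id="c", cpd_name="compound c", rt_min=20.0, rt_max=80.0,
               mz_min=150.0, mz_max=150.1, rt=50.0, mz=150.05)


@pytest.fixture
def emg_recipe():
    """One EMG peak, mild noise, fixed seed."""
    return RunRecipe(
        n_scans=80, rt_start=0.0, scan_interval=1.0,
        peaks=[PeakSpec(cpd_id="X", mz=150.05, mu=40.0, sigma=3.0,
                        amplitude=1e5, tau=2.0)],
        noise_sd=200.0, baseline=500.0, mz_jitter_sd=0.001, seed=7,
        sample_id="s0")


@pytest.fixture
def emg_run(emg_recipe):
    return simulate_run(emg_recipe)


def naive_emg(t, A, mu, sigma, tau):
    """Independent (overflow-prone but exact) EMG reference implementation."""
    from scipy.special import erfc
    t = np.asarray(t, dtype=float)
    return (A * sigma / tau) * math.sqrt(math.pi / 2.0) * np.exp(
        sigma**2 / (2 * tau**2) - (t - mu) / tau
    ) * erfc((sigma / tau - (t - mu) / sigma) / math.sqrt(2.0))


def naive_skewed_gaussian(t, A, mu, sigma, alpha):
    from scipy.special import erf
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma
    return A * np.exp(-0.5 * z * z) * (1.0 + erf(alpha * z / math.sqrt(2.0)))
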