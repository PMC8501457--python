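import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phasorflim.io import AcquisitionMeta
from phasorflim.phasor import TransformConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def meta() -> AcquisitionMeta:
    """Default acquisition: 256 bins over one 10-ns period at 100 MHz."""
    return AcquisitionMeta()


@pytest.fixture(scope="session")
def tcfg() -> TransformConfig:
    return TransformConfig()


def noise_free_histogram(taus, amps, meta: AcquisitionMeta, total=1e6,
                         sampling="integral"):
    """Noise-free discretized wrapped multi-exponential decay.

    ``integral`` integrates the wrapped density over each bin (what a
    detector records); ``center`` samples the density at bin centers (the
    discrete model the fitter uses).
    """
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    amps = np.atleast_1d(np.asarray(amps, dtype=float))
    T = meta.period_ns
    edges = np.arange(meta.n_bins + 1) * meta.bin_width_ns
    y = np.zeros(meta.n_bins)
    for a, tau in zip(amps, taus):
        wrap = 1.0 / (1.0 - np.exp(-T / tau))
        if sampling == "integral":
            cdf = -tau * np.exp(-edges / tau)
            y += a * wrap * np.diff(cdf)
        else:
            centers = 0.5 * (edges[:-1] + edges[1:])
            y += a * wrap * np.exp(-centers / tau)
    return y * (total / y.sum())
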