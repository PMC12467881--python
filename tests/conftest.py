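import numpy as np
import pytest

from libsbridge.simulate import high_res_instrument, low_res_instrument
from libsbridge.spectra import LabeledSpectrumSet, Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_spectrum():
    wl = np.linspace(300.0, 400.0, 101)
    return Spectrum(wl, np.sin(wl / 10.0) + 2.0, "test")


@pytest.fixture
def small_set(rng):
    """Tiny labeled set: 2 classes x 4 spectra on one grid."""
    wl = np.linspace(300.0, 400.0, 201)
    rows, labels, meta = [], [], []
    for c, level in (("A", 1.0), ("B", 2.0)):
        for k in range(4):
            rows.append(level * np.exp(-0.5 * ((wl - 350.0) / 2.0) ** 2) + 0.01 * rng.normal(size=wl.size))
            labels.append(c)
            meta.append({"sample": f"{c}-0", "shot": k})
    return LabeledSpectrumSet(wl, np.vstack(rows), labels, "test", meta)


def tiny_instruments():
    """Coarse, fast instrument pair; FWHM scaled with the grid pitch so the
    pixels-per-resolution-element ratio matches the default instruments."""
    low = low_res_instrument(n_points=2048, fwhm_nm=0.5)
    high = high_res_instrument(n_points=21000, fwhm_nm=0.075, shift_nm=0.12)
    return low, high
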