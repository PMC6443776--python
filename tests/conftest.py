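import numpy as np
import pytest

from silkstruct import synthgen


@pytest.fixture(scope="session")
def default_lamellar_profile():
    """Noiseless two-phase lamellar profile with the study-like geometry
    (L_p = 38.5 nm, phase-I thickness 15.7 nm, 5 orders)."""
    params = synthgen.LamellarModelParams(
        long_period=38.5, phase1_fraction=15.7 / 38.5, n_orders=5,
    )
    return synthgen.generate_saxs_meridional(params)


@pytest.fixture(scope="session")
def default_waxd_profile():
    params = synthgen.default_waxd_params(crystallinity_true=0.44)
    return synthgen.generate_waxd_profile(params)


@pytest.fixture(scope="session")
def small_diagram_kwargs():
    """Compact geometry for 2D tests: full 10–37 deg coverage at 512²."""
    return {"image_shape": (512, 512), "camera_distance": 30.0,
            "pixel_size": 0.1}


def square_wave_autocorrelation(long_period, phase1_fraction, z_max=100.0,
                                dz=0.005, n_periods=200):
    """Independent oracle: direct numerical autocorrelation of the
    generating square-wave density profile η(z), via FFT over many
    periods.  Returns (lag, autocorrelation)."""
    z = np.arange(0.0, n_periods * long_period, dz)
    eta = ((z % long_period) < phase1_fraction * long_period).astype(float)
    eta -= eta.mean()
    n = eta.size
    f = np.fft.rfft(eta)
    ac = np.fft.irfft(f * np.conj(f), n=n) / n
    lag = np.arange(ac.size) * dz
    keep = lag <= z_max
    return lag[keep], ac[keep]
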