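import numpy as np
import pytest

from tnt.config import KineticsConfig, SimulationConfig
from tnt.simulate import _render_emitter


@pytest.fixture
def small_config():
    return SimulationConfig(
        field_size_px=(64, 64), n_z_planes=7, duration_s=200.0, n_mrna=3,
        diffusion_coeff_um2_s=0.02, rng_seed=42,
    )


@pytest.fixture
def runoff_kinetics():
    return KineticsConfig(elongation_rate_aa_s=2.0, silencing_time_s=0.0)


def make_spot_field(n_spots=10, snr=5.0, seed=0, size=128, sigma=1.3,
                    bg=10.0, gain=2.0, read_noise=1.5, min_sep=12.0):
    """Render a noisy 2-D field of well-separated Gaussian spots.

    SNR is the spot's peak photon signal over the background shot-noise SD.
    Returns (image, (n,2) array of true xy positions).
    """
    rng = np.random.default_rng(seed)
    peak = snr * np.sqrt(bg)
    photons = peak * 2.0 * np.pi * sigma**2
    pts = []
    while len(pts) < n_spots:
        p = rng.uniform(15, size - 15, 2)
        if all(np.hypot(*(p - q)) > min_sep for q in pts):
            pts.append(p)
    vol = np.zeros((1, size, size))
    for x, y in pts:
        _render_emitter(vol, x, y, 0.0, photons, sigma, 1.0)
    img = rng.poisson(vol[0] + bg).astype(float) * gain \
        + rng.normal(0.0, read_noise, (size, size))
    return img, np.array(pts)
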