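import numpy as np
import pytest

from wavetrace import synthetic as syn
from wavetrace.scan import ScanGeometry, scan_stack


PIXEL = 12.0  # um/px used by the standard local-wave fixture


def local_params(**overrides) -> syn.LocalWaveParams:
    """Standard local-wave generator config: threshold very low relative to
    the kernel peak so the front follows a near-sqrt(t) law and stays inside
    the image for the whole movie."""
    defaults = dict(
        D_true=116.0,
        source_mass=4 * np.pi * 116.0 * 1e10 * 1e-3,  # C = M/(4 pi D theta) = 1e10 s
        activation_threshold=1e-3,
        pixel_size=PIXEL,
        image_size=256,
        origin=(128.0, 128.0),
        n_frames=125,
        n_baseline_frames=5,
        noise_sd=0.0,
        rng_seed=0,
    )
    defaults.update(overrides)
    return syn.LocalWaveParams(**defaults)


@pytest.fixture(scope="session")
def small_local_wave():
    """A small noiseless local-wave stack with its ground truth and radial
    profiles, shared across tests (generation is the slow part)."""
    params = local_params(image_size=128, origin=(64.0, 64.0), n_frames=45,
                          n_baseline_frames=5, pixel_size=16.0)
    stack, truth = syn.gen_local_wave_stack(params)
    geom = ScanGeometry("radial_point", [(64.0, 64.0)], n_lines=100,
                        line_length=63 * 16.0)
    profiles = scan_stack(stack, geom)
    return params, stack, truth, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
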