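import numpy as np
import pytest

from stentrec.core import Centerline
from stentrec.phantom import default_phantom_spec, deploy_stent, simulate_pullback


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless straight phantom: 3.0 mm stent, no shadow, no jitter."""
    spec = default_phantom_spec(seed=3, jitter_sd=0.0, shadow_width_deg=0.0)
    truth = deploy_stent(spec)
    frames = simulate_pullback(truth)
    return spec, truth, frames


@pytest.fixture(scope="session")
def noisy_phantom():
    """Straight phantom at study conditions: 0.03 mm jitter, 30 deg shadow."""
    spec = default_phantom_spec(seed=4)
    truth = deploy_stent(spec)
    frames = simulate_pullback(truth)
    return spec, truth, frames


@pytest.fixture()
def straight_centerline():
    z = np.linspace(0.0, 20.0, 401)
    return Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))


def circle_contour(r=1.5, n=200, center=(0.0, 0.0)):
    th = 2 * np.pi * np.arange(n) / n
    from stentrec.core import Contour2D

    return Contour2D(
        np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    )
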