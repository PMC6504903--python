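import math

import numpy as np
import pytest

from torusalign.geometry import RingPose, ring_point
from torusalign.io import ParticleSeed
from torusalign.simulate import SceneSpec, simulate_toroid_volume


def seeds_from_truth(pose: RingPose, rng=None, jitter: float = 2.0,
                     particle_id: str = "p0") -> ParticleSeed:
    """Clicked-point seeds at the ring's 0/90/180/270-degree travel angles,
    optionally jittered, as an annotator would place them."""
    pts = ring_point(pose, np.array([0.0, math.pi / 2, math.pi,
                                     3 * math.pi / 2]))[:, :2]
    if rng is not None and jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, pts.shape)
    return ParticleSeed(particle_id, "sim", pts)


@pytest.fixture(scope="session")
def standard_scene():
    """One SIM-like toroid scene shared by read-only tests."""
    spec = SceneSpec(diameter_nm=160.0, theta_deg=20.0, phi_deg=60.0, seed=1)
    vol, truth = simulate_toroid_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    spec = SceneSpec(
        diameter_nm=160.0, theta_deg=25.0, phi_deg=110.0, seed=2,
        poisson=False, read_noise_sd=0.0,
    )
    vol, truth = simulate_toroid_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def standard_fit(standard_scene):
    """Fit of the standard scene (computed once per session)."""
    from torusalign.fitting import TiltedRingModel

    _, vol, truth = standard_scene
    seed = seeds_from_truth(truth.pose, np.random.default_rng(2))
    model = TiltedRingModel.from_volume(vol, seed)
    return model, model.fit(), truth
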