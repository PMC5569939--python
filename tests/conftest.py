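import numpy as np
import pytest

import palsymetry as pm


@pytest.fixture(scope="session")
def bundle():
    """Small synthetic morphable model shared across tests (read-only)."""
    return pm.make_model(pm.SyntheticConfig(m=200, k_id=8, k_exp=4, seed=1))


@pytest.fixture(scope="session")
def scheme():
    return pm.ibug_68()


def synthetic_observation(bundle, seed, noise_sigma=0.0, exp_scale=0.5):
    """Ground-truth (pose, coeffs, observation) triple for recovery tests."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    coeffs = pm.ShapeCoefficients(
        alpha_id=rng.standard_normal(bundle.model.k_id),
        alpha_exp=exp_scale * rng.standard_normal(bundle.model.k_exp),
    )
    pose = pm.Pose(
        scale=float(2.0 + rng.random()),
        pitch=float(rng.uniform(-0.2, 0.2)),
        yaw=float(rng.uniform(-0.25, 0.25)),
        roll=float(rng.uniform(-0.15, 0.15)),
        translation=rng.uniform(200, 300, size=2),
    )
    mesh = pm.construct_shape(bundle.model, coeffs)
    obs = pm.observe(
        mesh, pose, bundle.correspondence,
        noise_sigma=noise_sigma, seed=int(rng.integers(2**31)), scheme=bundle.scheme,
    )
    return pose, coeffs, obs
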