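import warnings

import numpy as np
import pytest

import lungexpand as lx

warnings.filterwarnings("ignore", message="only .* boundary voxels")
warnings.filterwarnings("ignore", message="demons diverging")


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: same 192 mm organ as the default, 4 mm voxels."""
    return lx.PhantomSpec(grid_shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0),
                          seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return lx.make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_pair(small_phantom):
    exp_vol, exp_mask, truth = small_phantom
    insp_vol, insp_mask, lm = lx.warp_to_inspiration(exp_vol, truth)
    return dict(exp_vol=exp_vol, exp_mask=exp_mask, truth=truth,
                insp_vol=insp_vol, insp_mask=insp_mask, landmarks=lm)


@pytest.fixture(scope="session")
def registered_small(small_pair):
    """Full three-stage chain on the small phantom (shared across tests)."""
    from lungexpand.cohort import register_pair
    p = small_pair
    obs = lx.observed_landmarks(p["landmarks"], 1.0, seed=100)
    eseg = lx.segment_lung(p["exp_vol"])
    iseg = lx.segment_lung(p["insp_vol"])
    chains, qc = register_pair(p["exp_vol"], p["insp_vol"], eseg, iseg, obs,
                               tps_kinds="bronchial", seed=0)
    return dict(chains=chains, qc=qc, observed=obs, exp_seg=eseg,
                insp_seg=iseg, **p)


def rng_points(seed, n, lo=0.0, hi=100.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n, 3))
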