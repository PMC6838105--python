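import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import rhizoct as rc


@pytest.fixture(scope="session")
def compaction_phantom():
    """One 500 µm root with a compaction halo (A_c=0.10, L_c=300 µm) in a
    10 %-porosity matrix at 19 µm voxels — the standard study condition."""
    cfg = rc.single_tube_config(
        shape=(128, 128, 128), seed=1, halo=rc.HaloParams(A_c=0.10, L_c=300.0)
    )
    gray, truth = rc.generate_phantom(cfg)
    return cfg, gray, truth


@pytest.fixture(scope="session")
def wall_phantom():
    """One 500 µm root with a wall-excess halo (A_w=0.08, L_w=60 µm) only."""
    cfg = rc.single_tube_config(
        shape=(96, 96, 96), seed=2, halo=rc.HaloParams(A_w=0.08, L_w=60.0)
    )
    gray, truth = rc.generate_phantom(cfg)
    return cfg, gray, truth


@pytest.fixture(scope="session")
def two_phase_phantom():
    """Tube-free granular matrix phantom at 10 % porosity."""
    cfg = rc.GeneratorConfig(shape=(96, 96, 96), seed=7, target_porosity=0.10)
    gray, truth = rc.generate_phantom(cfg)
    return cfg, gray, truth


def cylinder_mask(shape, radius_vox, axis=0):
    """Boolean cylinder along an axis, centered on a voxel (odd-symmetric,
    which keeps 3D thinning well-behaved)."""
    idx = np.indices(shape, dtype=float)
    plane = [i for i in range(3) if i != axis]
    c = [s // 2 for s in shape]
    r2 = (idx[plane[0]] - c[plane[0]]) ** 2 + (idx[plane[1]] - c[plane[1]]) ** 2
    return r2 <= radius_vox**2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
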