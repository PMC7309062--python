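import logging

import numpy as np
import pytest

import ecgist as e

logging.getLogger("ecgist").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ico_mesh() -> e.SurfaceMesh:
    return e.generate_sphere_mesh(12, seed=0)


@pytest.fixture(scope="session")
def small_mesh() -> e.SurfaceMesh:
    return e.generate_sphere_mesh(120, seed=7)


@pytest.fixture(scope="session")
def small_layout(small_mesh) -> e.RegionLayout:
    return e.assign_regions(small_mesh, {"scar": 0, "valve": 60},
                            {"scar": 2, "border": 4, "valve": 2})


@pytest.fixture(scope="session")
def small_cfg() -> e.SynthConfig:
    return e.SynthConfig(node_count=120, fs=2048.0, n_beats=6,
                         rr_interval_s=1.0, rng_seed=7)


@pytest.fixture(scope="session")
def small_study(small_mesh, small_layout, small_cfg):
    """Noiseless synthetic recording with exact ground truth."""
    rec, ann = e.synthesize_recording(small_mesh, small_layout, small_cfg)
    return small_mesh, small_layout, small_cfg, rec, ann
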