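import numpy as np
import pytest

from coilvar.config import load_config
from coilvar.structure import CrickParams, build_coiled_coil


@pytest.fixture(scope="session")
def default_cfg():
    return load_config()


@pytest.fixture(scope="session")
def reference_bundle(tmp_path_factory):
    """Full pipeline run on the packaged default configuration (slow; shared)."""
    from coilvar.impact import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(out_dir=out)


@pytest.fixture(scope="session")
def reference_structure(default_cfg):
    from coilvar.impact import build_reference_structure

    return build_reference_structure(default_cfg)


@pytest.fixture(scope="session")
def small_coil():
    """42-residue poly-heptad dimer, noise-free."""
    seq = ("LAELKNE" * 6)[:42]
    return build_coiled_coil(seq, seq, CrickParams(), (1, "a"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform random rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
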