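import numpy as np
import pytest

from tfdyn.structures import AMINO, Structure


def make_structure(coords, chain="A", kind=AMINO, names=None, resnums=None):
    """Bare structure around a coordinate array (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return Structure(
        coords=coords,
        node_kind=np.full(n, kind),
        chain_id=np.full(n, chain),
        residue_number=np.arange(1, n + 1) if resnums is None else np.asarray(resnums),
        residue_name=np.full(n, "GLY") if names is None else np.asarray(names),
    )


def random_structure(n, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return make_structure(rng.uniform(-scale, scale, size=(n, 3)))


def random_rotation(seed=0):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture(scope="session")
def tf_like():
    """Default three-domain chain with its domain map (seed 0)."""
    from tfdyn.synthetic import ToySpec, make_hinge_structure

    spec = ToySpec(seed=0)
    structure, domains = make_hinge_structure(spec)
    return spec, structure, domains


@pytest.fixture(scope="session")
def two_domain():
    """Two-domain tweezer toy (seed 0)."""
    from tfdyn.synthetic import ToySpec, make_hinge_structure

    spec = ToySpec(seed=0, n_domains=2, domain_sizes=(40, 40),
                   domain_names=("BD", "HD"))
    structure, domains = make_hinge_structure(spec)
    return spec, structure, domains


@pytest.fixture(scope="session")
def anchored(tf_like):
    from tfdyn.synthetic import make_anchored_surface

    spec, _, _ = tf_like
    return make_anchored_surface(spec)
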