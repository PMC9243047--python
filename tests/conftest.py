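import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from anomerthermo.backends import SurrogateBackend, SurrogateParams
from anomerthermo.chem_core import DihedralSpec, Geometry, place_atom
from anomerthermo.synthetic import toy_molecule

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def butane_like():
    """Four-carbon chain with a single driveable central torsion at 60°."""
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([1.5, 0.0, 0.0])
    p2 = p1 + np.array([0.6, 1.4, 0.0])
    p3 = place_atom(p2, p1, p0, 1.5, 112.0, 60.0)
    geom = Geometry(("C", "C", "C", "C"), np.array([p0, p1, p2, p3]))
    return geom, DihedralSpec(3, 2, 1, 0, label="chain torsion")


@pytest.fixture(scope="session")
def torsion_toy_backend(butane_like):
    """Surrogate with one 3-fold torsion (barrier 2 kcal/mol, phase 0) plus
    harmonic bond/angle terms; minima at ±60° and 180°."""
    geom, spec = butane_like
    c = geom.coords
    d = lambda a, b: float(np.linalg.norm(c[a] - c[b]))
    params = SurrogateParams(
        bonds=(
            (0, 1, 300.0, d(0, 1)),
            (1, 2, 300.0, d(1, 2)),
            (2, 3, 300.0, d(2, 3)),
            (0, 2, 60.0, d(0, 2)),
            (1, 3, 60.0, d(1, 3)),
        ),
        torsions=((0, 1, 2, 3, 2.0, 3, 0.0),),
    )
    return SurrogateBackend(params)


@pytest.fixture(scope="session")
def furanose():
    return toy_molecule("toy-furanose")


@pytest.fixture(scope="session")
def furanose_backend(furanose):
    geom, _ = furanose
    return SurrogateBackend(SurrogateParams.from_geometry(geom))
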