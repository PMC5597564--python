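import numpy as np
import pytest

from cepdock import (
    Atom,
    EnergyModelParams,
    LigandTopology,
    ReceptorModel,
    TorsionNode,
)
from cepdock.synthetic import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def three_atom_topo():
    """3-atom ligand with one torsion about the z-aligned 0-1 bond; the
    terminal atom 2 sits off-axis so the torsion visibly moves it."""
    return LigandTopology(
        atoms=(
            Atom(0, "C", "C", (0.0, 0.0, 0.0)),
            Atom(1, "C", "C", (0.0, 0.0, 1.0)),
            Atom(2, "C", "C", (1.0, 0.0, 1.0)),
        ),
        bonds=((0, 1), (1, 2)),
        torsion_nodes=(TorsionNode(0, 1, frozenset({2})),),
        root_atoms=(0,),
    )


@pytest.fixture(scope="session")
def rigid_pair_topo():
    """2-atom rigid ligand at the origin, used for translation checks."""
    return LigandTopology(
        atoms=(
            Atom(0, "C", "C", (0.0, 0.0, 0.0)),
            Atom(1, "C", "C", (1.0, 0.0, 0.0)),
        ),
        bonds=((0, 1),),
    )


@pytest.fixture(scope="session")
def small_box_receptor():
    return ReceptorModel(
        atoms=(Atom(0, "C", "C", (0.0, 0.0, 4.0), charge=0.1),),
        bounding_box=((0.0, 0.0, 0.0), (8.0, 8.0, 8.0)),
    )


@pytest.fixture(scope="session")
def params():
    return EnergyModelParams()


@pytest.fixture(scope="session")
def fixture_t2():
    """A T=2 planted-pocket instance used across unit tests.

    Built without the generator's probe-based quality control: unit tests
    need a structurally valid docking problem, not a certified benchmark
    (the recovery acceptance tests build fully screened fixtures).
    """
    return make_fixture(FixtureSpec(n_torsions=2, rng_seed=0), quality_control=False)


def random_pose_topology(rng: np.random.Generator, n_torsions: int = 3):
    """Random branched topology for property tests (delegates to the
    synthetic generator so tests exercise realistic torsion trees)."""
    spec = FixtureSpec(n_torsions=n_torsions, rng_seed=int(rng.integers(2**31)))
    return make_fixture(spec, quality_control=False).topo
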