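import numpy as np
import pytest

from brnib import CavityAtom, FixtureSpec, NIBModel, Pose, build_fixture

#: Small, fast study conditions used by most unit tests; the full default
#: conditions are exercised by the recovery/determinism tests.
SMALL_SPEC = FixtureSpec(
    n_signal_atoms=6,
    n_noise_atoms=6,
    n_actives=10,
    n_decoys=60,
    poses_per_compound=2,
    seed=7,
)


@pytest.fixture(scope="session")
def small_fixture():
    return build_fixture(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_fixture():
    return build_fixture(FixtureSpec())


def random_atoms(rng: np.random.Generator, n: int, span: float = 3.0,
                 charged: bool = True) -> list[CavityAtom]:
    """Random atom list for property tests."""
    elements = rng.choice(["C", "N", "O", "H", "S"], size=n)
    atoms = []
    for el in elements:
        q = float(rng.uniform(-0.5, 0.5)) if charged else 0.0
        atoms.append(CavityAtom(str(el), rng.uniform(-span, span, size=3), q))
    return atoms


def random_model(rng: np.random.Generator, n: int, **kw) -> NIBModel:
    return NIBModel("random", random_atoms(rng, n, **kw))


def random_pose(rng: np.random.Generator, n: int, **kw) -> Pose:
    return Pose("random", 0, random_atoms(rng, n, **kw))
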