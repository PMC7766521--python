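import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import deutbind as db
from deutbind.core import Atom, Structure
from deutbind.simgen import SolvationSpec

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def histamine_trans():
    return db.build_histamine(side_torsion=158.8)


@pytest.fixture(scope="session")
def histamine_gauche():
    return db.build_histamine(side_torsion=62.1)


@pytest.fixture(scope="session")
def pocket(histamine_gauche):
    return db.make_pocket_complex(histamine_gauche, seed=3)


@pytest.fixture(scope="session")
def solvated(histamine_trans):
    spec = SolvationSpec(
        n_water=8, geometry="sphere", radius=6.5, placed_contacts=[("N2", 2.8)]
    )
    return db.solvate(histamine_trans, spec, seed=1)


def make_water(origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0),
               res_number=1):
    """A rigid 3-site water with its O at origin and hydrogens opening
    along +direction (helper for hand-built fixtures)."""
    import math

    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0], 0.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    half = math.radians(104.52 / 2)
    o = np.asarray(origin, dtype=float)
    h1 = o + 0.9572 * (math.cos(half) * d + math.sin(half) * perp)
    h2 = o + 0.9572 * (math.cos(half) * d - math.sin(half) * perp)
    atoms = [
        Atom("O", "O", "HOH", res_number, "W"),
        Atom("H", "H1", "HOH", res_number, "W"),
        Atom("H", "H2", "HOH", res_number, "W"),
    ]
    return Structure(atoms, np.vstack([o, h1, h2]))


def merge(*structures):
    """Concatenate structures into one (fixture helper)."""
    atoms = []
    coords = []
    for s in structures:
        atoms.extend(s.atoms)
        coords.append(s.coords)
    return Structure(atoms, np.vstack(coords))
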