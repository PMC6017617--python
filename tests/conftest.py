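import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from polmem import fixtures


@pytest.fixture
def toy_system():
    """Deterministic 6-site neutral toy molecule."""
    return fixtures.gen_toy_molecule(fixtures.ToyMoleculeSpec(seed=11, n_sites=6))


@pytest.fixture
def anionic_system():
    """5-site toy molecule with net charge −1 (phosphate-like fragment)."""
    return fixtures.gen_toy_molecule(
        fixtures.ToyMoleculeSpec(seed=5, n_sites=5, net_charge=-1)
    )


@pytest.fixture
def small_bilayer():
    """Compact bilayer trajectory for the analysis tests."""
    spec = fixtures.BilayerSpec(
        seed=3, n_lipid=24, n_water=500, n_frames=4, box_xy=30.0,
        box_z=70.0, n_chain_carbons=6,
    )
    return fixtures.gen_bilayer_traj(spec)


def chain_coords(rng, n, dmin=2.5, step=(2.5, 3.5)):
    """Random chain geometry with a guaranteed minimum pairwise
    separation (rejection sampling), so fixtures stay physically
    plausible."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        d = rng.uniform(*step) * rng.choice([-1.0, 1.0], 3)
        cand = pts[-1] + d
        if all(np.linalg.norm(cand - p) >= dmin for p in pts):
            pts.append(cand)
    return np.array(pts)


def random_multipole(rng, charge_scale=1.0, dipole_scale=0.3, quad_scale=0.2):
    from polmem.mpole import Multipole

    q = rng.uniform(-charge_scale, charge_scale)
    mu = rng.normal(0.0, dipole_scale, 3)
    raw = rng.normal(0.0, quad_scale, (3, 3))
    Q = 0.5 * (raw + raw.T)
    Q -= np.trace(Q) / 3.0 * np.eye(3)
    return Multipole(q, mu, Q)
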