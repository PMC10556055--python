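import math

import numpy as np
import pytest

from clawpore import EnergyParams, compute_landscape
from clawpore.structures import BeadModel
from clawpore.synthetic_data import make_toy_monomer

COULOMB = 138.935458  # kJ mol^-1 nm e^-2


def bead_model(positions, charges=None, radii=None, names=None, label="toy"):
    """Small hand-built bead model for oracle tests."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    charges = np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
    radii = np.full(n, 2.0) if radii is None else np.asarray(radii, dtype=float)
    if names is None:
        names = ["LYS" if q > 0 else "ASP" if q < 0 else "GLY" for q in charges]
    return BeadModel(
        residue_indices=np.arange(1, n + 1),
        residue_names=list(names),
        chain_ids=["A"] * n,
        positions=positions,
        radii=radii,
        charges=charges,
        label=label,
    )


def brute_force_energy(pos_a, q_a, pos_b, q_b, params: EnergyParams):
    """Double-loop LJ + Coulomb oracle, independent of the vectorized kernel.

    Terms are accumulated with math.fsum so the oracle itself carries no
    summation-order error.
    """
    lj_terms = []
    coul_terms = []
    for i in range(len(pos_a)):
        for j in range(len(pos_b)):
            r = math.dist(pos_a[i], pos_b[j])
            if r > params.cutoff:
                continue
            sr6 = (params.sigma / r) ** 6
            lj_terms.append(4.0 * params.epsilon * (sr6**2 - sr6))
            coul_terms.append(
                COULOMB * q_a[i] * q_b[j] / (params.eps_r * (r / 10.0))
            )
    e_lj = math.fsum(lj_terms)
    e_coul = math.fsum(coul_terms)
    return e_lj, e_coul, e_lj + e_coul


def random_bead_pair(seed, n=50):
    """Random 50-bead groups with physical separation (no near-overlaps).

    The second group is shifted along +x until the closest pair is at
    least 2 A apart, as in any contact-placed pose.
    """
    rng = np.random.default_rng(seed)
    pos_a = rng.uniform(-8, 8, (n, 3))
    pos_b = rng.uniform(-8, 8, (n, 3)) + [17.0, 0.0, 0.0]
    q_a = rng.choice([-1.0, 0.0, 1.0], n)
    q_b = rng.choice([-1.0, 0.0, 1.0], n)
    def min_dist():
        diff = pos_a[:, None] - pos_b[None, :]
        return float(np.sqrt((diff**2).sum(-1)).min())

    while min_dist() < 2.0:
        pos_b = pos_b + [0.5, 0.0, 0.0]
    return pos_a, q_a, pos_b, q_b


@pytest.fixture(scope="session")
def monomer_a():
    return make_toy_monomer(
        seed=1, ecl_charges=[("ECS1", 2, 1), ("ECS1", 7, -1)], label="toyA"
    )


@pytest.fixture(scope="session")
def monomer_b():
    return make_toy_monomer(
        seed=2, ecl_charges=[("ECS1", 3, -1), ("ECS2", 1, 1)], label="toyB"
    )


@pytest.fixture(scope="session")
def landscape_1deg(monomer_a, monomer_b):
    """Full 1-degree rotational landscape shared by the acceptance checks."""
    return compute_landscape(monomer_a, monomer_b, increment=1.0)
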