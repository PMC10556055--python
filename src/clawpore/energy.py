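"""Coarse-grained non-bonded interaction energies.

Bead-bead energies are a 12-6 Lennard-Jones term plus a screened Coulomb
term,

    E_LJ   = sum 4*eps * [(sigma/r)^12 - (sigma/r)^6]
    E_Coul = sum f * q_i * q_j / (eps_r * r_nm)

summed over inter-group pairs within the cutoff, with
f = 138.935458 kJ mol^-1 nm e^-2 (r in nm in the Coulomb term).  Negative
totals indicate stable association.  Defaults are MARTINI-like magnitudes:
sigma 4.7 A, eps 2.0 kJ/mol, relative dielectric 15, cutoff 12 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyParams", "pair_energy", "COULOMB_CONSTANT"]

#: kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458

#: below this separation the LJ term is treated as singular
OVERLAP_GUARD = 0.1  # Angstrom


class OverlapError(ValueError):
    """Two beads closer than the singularity guard."""


@dataclass(frozen=True)
class EnergyParams:
    sigma: float = 4.7        # A
    epsilon: float = 2.0      # kJ/mol
    eps_r: float = 15.0       # relative dielectric
    cutoff: float = 12.0      # A

    def __post_init__(self):
        if min(self.sigma, self.epsilon, self.eps_r, self.cutoff) <= 0:
            raise ValueError("all energy parameters must be positive")


def pair_energy(pos_a, charges_a, pos_b, charges_b, params: EnergyParams = None):
    """(E_LJ, E_Coul, E_total) in kJ/mol between two bead groups.

    Positions in Angstrom, charges in elementary charges.  Pairs beyond the
    cutoff contribute nothing; a pair below the overlap guard raises
    :class:`OverlapError`.
    """
    params = params or EnergyParams()
    pos_a = np.atleast_2d(np.asarray(pos_a, dtype=float))
    pos_b = np.atleast_2d(np.asarray(pos_b, dtype=float))
    qa = np.atleast_1d(np.asarray(charges_a, dtype=float))
    qb = np.atleast_1d(np.asarray(charges_b, dtype=float))

    diff = pos_a[:, None, :] - pos_b[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))
    if np.any(r < OVERLAP_GUARD):
        raise OverlapError(
            f"bead pair separation below {OVERLAP_GUARD} A (singularity guard)"
        )
    within = r <= params.cutoff
    if not np.any(within):
        return 0.0, 0.0, 0.0
    rr = r[within]
    sr6 = (params.sigma / rr) ** 6
    e_lj = float(np.sum(4.0 * params.epsilon * (sr6**2 - sr6)))
    qq = np.outer(qa, qb)[within]
    e_coul = float(np.sum(COULOMB_CONSTANT * qq / (params.eps_r * (rr / 10.0))))
    return e_lj, e_coul, e_lj + e_coul
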