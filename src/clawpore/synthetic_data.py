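"""Synthetic claudin-like structures and electrophysiology with known truth.

Every generator is seed-deterministic and emits its ground truth alongside
the data, so each downstream stage — landscapes, assembly, pore profiling,
residue tallies, GHK inversions, flux regression — can be validated without
any external structures or measurements.

* :func:`make_toy_monomer` builds a claudin-like fold: four transmembrane
  bead columns spanning the membrane slab plus two extracellular arcs
  (ECS1 longer than ECS2) decorated with user-placed charges.
* :func:`make_ring_stack` builds coaxial bead rings whose maximal in-plane
  probe radius is known analytically; it is the oracle for the pore
  profiler.
* :func:`make_ephys_record` forward-simulates dilution and bi-ionic
  potentials with the GHK relation at 37 C.
* :func:`make_flux_series` simulates tracer appearance under the sink
  assumption, Q(t) = P_app * A * C0 * t.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .electrophysiology import (
    BathComposition,
    DILUTED_RINGER,
    FluxSeries,
    LITHIUM_RINGER,
    RINGER,
    ghk_potential,
)
from .structures import DEFAULT_BEAD_RADIUS, BeadModel, MembraneFrame

__all__ = [
    "make_toy_monomer",
    "make_ring_stack",
    "RingStackTruth",
    "make_ephys_record",
    "EphysRecord",
    "make_flux_series",
]


def _arc(n: int, radius: float, z_lo: float, z_hi: float, phase: float):
    angles = phase + np.linspace(0.0, math.pi, n)
    zs = np.linspace(z_lo, z_hi, n)
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), zs]
    )


def make_toy_monomer(
    n_tm_residues_per_helix: int = 8,
    ecl_charges=(),
    seed: int = 0,
    n_ecs1: int = 10,
    n_ecs2: int = 6,
    membrane: MembraneFrame = None,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    jitter: float = 0.15,
    label: str = "toy",
) -> BeadModel:
    """Claudin-like toy monomer: four TM bead columns + two extracellular arcs.

    ``ecl_charges`` is a list of ``(segment, offset, charge)`` with segment
    "ECS1" or "ECS2", a 0-based offset into that arc, and charge +1 (placed
    as LYS) or -1 (ASP).  ``seed`` controls a small deterministic positional
    jitter so toys are not exactly symmetric.
    """
    if n_tm_residues_per_helix <= 0 or n_ecs1 <= 0 or n_ecs2 <= 0:
        raise ValueError("bead counts must be positive")
    if n_ecs1 <= n_ecs2:
        raise ValueError("ECS1 must be the longer extracellular segment")
    membrane = membrane or MembraneFrame()
    rng = np.random.default_rng(seed)

    # four TM columns on a rectangular cross-section
    corners = [(-4.0, -3.0), (4.0, -3.0), (4.0, 3.0), (-4.0, 3.0)]
    zs = np.linspace(membrane.z_min, membrane.z_max, n_tm_residues_per_helix)
    positions, names, segments = [], [], []
    for h, (cx, cy) in enumerate(corners, start=1):
        for z in zs:
            positions.append([cx, cy, z])
            names.append("ALA")
            segments.append(f"TM{h}")

    # extracellular arcs above the slab; ECS1 longer and wider than ECS2
    z_top = membrane.z_max
    ecs1 = _arc(n_ecs1, 6.0, z_top + 1.5, z_top + 5.0, phase=0.0)
    ecs2 = _arc(n_ecs2, 4.0, z_top + 1.0, z_top + 3.0, phase=math.pi)
    arc_names = {"ECS1": ["GLY"] * n_ecs1, "ECS2": ["GLY"] * n_ecs2}
    for segment, offset, charge in ecl_charges:
        if segment not in arc_names:
            raise ValueError(f"charges may only be placed on ECS arcs, not {segment!r}")
        arc = arc_names[segment]
        if not 0 <= int(offset) < len(arc):
            raise ValueError(
                f"offset {offset} outside {segment} (length {len(arc)})"
            )
        if charge == 1:
            arc[int(offset)] = "LYS"
        elif charge == -1:
            arc[int(offset)] = "ASP"
        else:
            raise ValueError("placed charges must be +1 or -1")
    for seg_name, arc in (("ECS1", ecs1), ("ECS2", ecs2)):
        for row, res in zip(arc, arc_names[seg_name]):
            positions.append(list(row))
            names.append(res)
            segments.append(seg_name)

    positions = np.asarray(positions, dtype=float)
    positions += jitter * rng.standard_normal(positions.shape)
    n = len(positions)
    indices = np.arange(1, n + 1)
    from .structures import residue_charge

    return BeadModel(
        residue_indices=indices,
        residue_names=names,
        chain_ids=["A"] * n,
        positions=positions,
        radii=np.full(n, bead_radius),
        charges=np.array([residue_charge(r) for r in names], dtype=float),
        segments={int(i): s for i, s in zip(indices, segments)},
        label=label,
    )


@dataclass(frozen=True)
class RingStackTruth:
    """Analytic per-slice probe radii for a coaxial ring stack."""

    ring_z: np.ndarray
    ring_radii: np.ndarray
    bead_radius: float
    clearance: np.ndarray     # signed analytic clearance per ring plane
    leaky: bool               # some inter-bead gap is open to a probe

    @property
    def min_probe_radius(self) -> float:
        return float(np.min(self.clearance))

    @property
    def min_diameter(self) -> float:
        return float(max(2.0 * self.min_probe_radius, 0.0))

    @property
    def pore_blocked(self) -> bool:
        return bool(np.any(self.clearance <= 0.0))

    def clearance_at(self, z: float) -> float:
        """Exact clearance of the axis point at height z (coaxial geometry)."""
        d = np.sqrt(self.ring_radii**2 + (self.ring_z - z) ** 2)
        return float(np.min(d) - self.bead_radius)


def make_ring_stack(
    ring_radii,
    beads_per_ring: int = 16,
    bead_radius: float = 2.0,
    z_spacing: float = 3.0,
    label: str = "ring-stack",
):
    """Coaxial bead rings with analytically known pore clearance.

    Returns ``(model, truth)``.  For tight walls (adjacent beads of a ring
    touching or overlapping, chord <= bead diameter) the in-plane clearance
    at a ring plane is exactly ``min_k sqrt(R_k^2 + dz_k^2) - bead_radius``
    (the axis is the maximizer); for a single ring plane this reduces to
    ``ring_radius - bead_radius``.  Leaky walls are flagged on the truth
    rather than given a fake ground truth.
    """
    ring_radii = np.asarray(ring_radii, dtype=float)
    if np.any(ring_radii < 0):
        raise ValueError("ring radii must be non-negative")
    if beads_per_ring < 6:
        raise ValueError("need at least 6 beads per ring")
    if bead_radius <= 0 or z_spacing < 0:
        raise ValueError("bead radius must be positive, spacing non-negative")

    n_rings = len(ring_radii)
    ring_z = z_spacing * np.arange(n_rings)
    angles = 2.0 * math.pi * np.arange(beads_per_ring) / beads_per_ring
    positions = []
    for z, radius in zip(ring_z, ring_radii):
        ring = np.column_stack(
            [radius * np.cos(angles), radius * np.sin(angles),
             np.full(beads_per_ring, z)]
        )
        positions.append(ring)
    positions = np.vstack(positions)
    n = len(positions)

    chords = 2.0 * ring_radii * math.sin(math.pi / beads_per_ring)
    leaky = bool(np.any(chords > 2.0 * bead_radius))
    clearance = np.array(
        [
            np.min(np.sqrt(ring_radii**2 + (ring_z - z) ** 2)) - bead_radius
            for z in ring_z
        ]
    )
    truth = RingStackTruth(
        ring_z=ring_z,
        ring_radii=ring_radii,
        bead_radius=bead_radius,
        clearance=clearance,
        leaky=leaky,
    )
    indices = np.arange(1, n + 1)
    model = BeadModel(
        residue_indices=indices,
        residue_names=["GLY"] * n,
        chain_ids=["A"] * n,
        positions=positions,
        radii=np.full(n, bead_radius),
        charges=np.zeros(n),
        segments={},
        label=label,
    )
    return model, truth


@dataclass(frozen=True)
class EphysRecord:
    """Forward-simulated dilution and bi-ionic potentials with ground truth."""

    dilution_potential_mv: float
    biionic_potential_mv: float
    teer_ohm_cm2: float
    apical: BathComposition
    basal_dilution: BathComposition
    basal_biionic: BathComposition
    temperature: float
    truth: dict

    def to_json(self, path) -> None:
        payload = {
            "dilution_potential_mv": self.dilution_potential_mv,
            "biionic_potential_mv": self.biionic_potential_mv,
            "teer_ohm_cm2": self.teer_ohm_cm2,
            "temperature_k": self.temperature,
            "truth": self.truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def make_ephys_record(
    true_p_na: float,
    true_p_cl: float,
    true_p_li: float,
    apical: BathComposition = RINGER,
    basal_dilution: BathComposition = DILUTED_RINGER,
    basal_biionic: BathComposition = LITHIUM_RINGER,
    teer: float = 224.0,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> EphysRecord:
    """Forward-GHK dilution and bi-ionic potentials plus Gaussian noise."""
    if min(true_p_na, true_p_cl, true_p_li) <= 0:
        raise ValueError("true permeabilities must be positive")
    rng = np.random.default_rng(seed)
    t = apical.temperature
    v_dil = ghk_potential(true_p_na, true_p_cl, apical, basal_dilution,
                          temperature=t)
    v_bi = ghk_potential(true_p_na, true_p_cl, apical, basal_biionic,
                         p_li=true_p_li, temperature=t)
    noise = rng.normal(0.0, noise_sd_mv, size=2) if noise_sd_mv > 0 else (0.0, 0.0)
    return EphysRecord(
        dilution_potential_mv=float(v_dil + noise[0]),
        biionic_potential_mv=float(v_bi + noise[1]),
        teer_ohm_cm2=float(teer),
        apical=apical,
        basal_dilution=basal_dilution,
        basal_biionic=basal_biionic,
        temperature=t,
        truth={
            "p_na_cm_s": true_p_na,
            "p_cl_cm_s": true_p_cl,
            "p_li_cm_s": true_p_li,
            "beta": true_p_na / true_p_cl,
            "p_li_over_p_na": true_p_li / true_p_na,
            "noise_sd_mv": noise_sd_mv,
            "seed": seed,
        },
    )


def make_flux_series(
    true_papp: float,
    area: float = 1.12,
    donor_conc: float = 200.0,
    receiver_volume: float = 1.5,
    timepoints_min=None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> FluxSeries:
    """Sink-condition tracer flux, Q(t) = P_app * A * C0 * t, with
    multiplicative Gaussian noise of fractional SD ``noise_frac``."""
    if true_papp < 0 or area <= 0 or donor_conc <= 0:
        raise ValueError("geometry and P_app must be positive")
    if timepoints_min is None:
        timepoints_min = np.arange(0.0, 181.0, 30.0)  # every 30 min for 3 h
    t = np.asarray(timepoints_min, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    q = true_papp * area * donor_conc * (t * 60.0)
    if noise_frac > 0:
        q = q * (1.0 + noise_frac * rng.standard_normal(t.shape))
    return FluxSeries(
        timepoints_min=t,
        receiver_amounts=q,
        donor_concentration=donor_conc,
        area=area,
        receiver_volume=receiver_volume,
    )
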