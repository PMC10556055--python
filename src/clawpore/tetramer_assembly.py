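"""Trans tetramer assembly from cis dimers.

Two cis dimers on opposing membranes interact head-on through their
extracellular segments to form the minimal paracellular channel unit.  The
second dimer is flipped 180 degrees about an in-membrane axis so its
extracellular side faces the first, laterally centred, and separated so the
facing extracellular surfaces sit a fixed gap apart.  Each dimer is treated
as a rigid group; the trans interface energy is the non-bonded energy summed
over bead pairs with one bead in each dimer, decomposed into Lennard-Jones
and Coulomb components.

The symmetric start can be locally refined over the four rigid degrees of
freedom of the flipped dimer (vertical gap, lateral x/y shift, twist about
z) with a deterministic Nelder-Mead descent; dimer-internal geometry is
never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .energy import EnergyParams, pair_energy
from .panel_landscape import Pose, _rot_z, place_at_contact
from .structures import BeadModel, write_pdb

__all__ = [
    "CisDimer",
    "TransTetramer",
    "build_tetramer",
    "refine_tetramer",
    "trans_interface_energy",
]

DEFAULT_TRANS_GAP = 2.0  # A, facing ECS surface separation

_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 degrees about the x axis


class AssemblyError(ValueError):
    """Steric clash or infeasible placement during tetramer assembly."""


@dataclass
class CisDimer:
    """Two monomers in a fixed side-by-side pose (world coordinates)."""

    model_a: BeadModel
    model_b: BeadModel
    label: str = ""

    @classmethod
    def from_pose(cls, model_a: BeadModel, model_b: BeadModel, pose: Pose,
                  label: str = "") -> "CisDimer":
        a, b = pose.apply(model_a, model_b)
        return cls(model_a=a, model_b=b, label=label or f"{a.label}/{b.label}")

    @classmethod
    def from_thetas(cls, model_a: BeadModel, model_b: BeadModel,
                    theta1: float, theta2: float, contact_gap: float = 0.5,
                    label: str = "") -> "CisDimer":
        pose = place_at_contact(model_a, model_b, theta1, theta2, contact_gap)
        return cls.from_pose(model_a, model_b, pose, label)

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([self.model_a.positions, self.model_b.positions])

    @property
    def radii(self) -> np.ndarray:
        return np.concatenate([self.model_a.radii, self.model_b.radii])

    @property
    def charges(self) -> np.ndarray:
        return np.concatenate([self.model_a.charges, self.model_b.charges])

    def ecs_mask(self) -> np.ndarray:
        masks = [m.segment_mask("ECS") for m in (self.model_a, self.model_b)]
        mask = np.concatenate(masks)
        if not mask.any():  # unlabeled structures: use the top 25% of beads
            z = self.positions[:, 2]
            mask = z >= np.quantile(z, 0.75)
        return mask

    def transformed(self, rotation=None, translation=None) -> "CisDimer":
        return CisDimer(
            model_a=self.model_a.transformed(rotation, translation),
            model_b=self.model_b.transformed(rotation, translation),
            label=self.label,
        )

    def internal_distances(self) -> np.ndarray:
        pos = self.positions
        return np.sqrt(np.sum((pos[:, None] - pos[None, :]) ** 2, axis=-1))


@dataclass
class TransTetramer:
    dimer_top: CisDimer      # flipped dimer, extracellular side facing down
    dimer_bottom: CisDimer   # as-built dimer, extracellular side facing up
    gap: float
    trans_mode: str = "homotypic"
    params: EnergyParams = field(default_factory=EnergyParams)

    @property
    def energies(self):
        return trans_interface_energy(self, self.params)

    def all_beads(self):
        """(positions, radii, charges, names, residue_indices, group_ids)."""
        models = [self.dimer_bottom.model_a, self.dimer_bottom.model_b,
                  self.dimer_top.model_a, self.dimer_top.model_b]
        pos = np.vstack([m.positions for m in models])
        radii = np.concatenate([m.radii for m in models])
        charges = np.concatenate([m.charges for m in models])
        names = sum((list(m.residue_names) for m in models), [])
        res_idx = np.concatenate([m.residue_indices for m in models])
        groups = np.concatenate(
            [np.full(len(m), g) for g, m in zip([0, 0, 1, 1], models)]
        )
        return pos, radii, charges, names, res_idx, groups

    def combined_model(self) -> BeadModel:
        """Single multi-chain model (chains A-D) for profiling and output."""
        models = [self.dimer_bottom.model_a, self.dimer_bottom.model_b,
                  self.dimer_top.model_a, self.dimer_top.model_b]
        chains = "ABCD"
        names, chain_ids, indices = [], [], []
        for ch, m in zip(chains, models):
            names.extend(m.residue_names)
            chain_ids.extend([ch] * len(m))
            indices.extend(m.residue_indices.tolist())
        return BeadModel(
            residue_indices=np.array(indices),
            residue_names=names,
            chain_ids=chain_ids,
            positions=np.vstack([m.positions for m in models]),
            radii=np.concatenate([m.radii for m in models]),
            charges=np.concatenate([m.charges for m in models]),
            segments={},
            label=f"{self.dimer_bottom.label}|{self.dimer_top.label}",
        )

    def write_pdb(self, path) -> None:
        write_pdb(self.combined_model(), path)


def _min_surface_separation(dimer_a: CisDimer, dimer_b: CisDimer) -> float:
    diff = dimer_a.positions[:, None, :] - dimer_b.positions[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))
    return float(np.min(r - dimer_a.radii[:, None] - dimer_b.radii[None, :]))


def build_tetramer(
    dimer_top: CisDimer,
    dimer_bottom: CisDimer,
    gap: float = DEFAULT_TRANS_GAP,
    trans_mode: str = "homotypic",
    params: EnergyParams = None,
) -> TransTetramer:
    """Place two cis dimers head-on across the paracellular gap.

    ``dimer_top`` is flipped 180 degrees about the x axis so its extracellular
    segments point down toward ``dimer_bottom``'s; centroids are laterally
    aligned and the vertical offset is chosen so the minimal facing
    ECS-to-ECS surface separation equals ``gap``.
    """
    if gap < 0:
        raise AssemblyError("trans gap must be non-negative")
    bottom = dimer_bottom
    flipped = dimer_top.transformed(rotation=_FLIP_X)

    # lateral centring
    shift_xy = bottom.positions.mean(axis=0) - flipped.positions.mean(axis=0)
    shift_xy[2] = 0.0
    flipped = flipped.transformed(translation=shift_xy)

    # vertical placement: facing ECS extremes separated by `gap`
    ecs_b = bottom.ecs_mask()
    ecs_t = flipped.ecs_mask()
    top_of_bottom = float(np.max(bottom.positions[ecs_b, 2] + bottom.radii[ecs_b]))
    bottom_of_top = float(np.min(flipped.positions[ecs_t, 2] - flipped.radii[ecs_t]))
    flipped = flipped.transformed(
        translation=[0.0, 0.0, top_of_bottom + gap - bottom_of_top]
    )

    sep = _min_surface_separation(bottom, flipped)
    if sep < 0:
        raise AssemblyError(
            f"steric overlap at requested gap (min separation {sep:.2f} A); "
            "try a larger gap"
        )
    return TransTetramer(
        dimer_top=flipped,
        dimer_bottom=bottom,
        gap=gap,
        trans_mode=trans_mode,
        params=params or EnergyParams(),
    )


def trans_interface_energy(tetramer: TransTetramer, params: EnergyParams = None):
    """(E_LJ, E_Coul, E_total) kJ/mol between the two dimer groups only.

    Intra-dimer pairs are excluded by construction: the sum runs over bead
    pairs with one bead in each cis dimer.
    """
    params = params or tetramer.params
    bottom, top = tetramer.dimer_bottom, tetramer.dimer_top
    return pair_energy(
        bottom.positions, bottom.charges, top.positions, top.charges, params
    )


def _placed_top(tetramer: TransTetramer, x: np.ndarray) -> CisDimer:
    dz, dx, dy, twist = x
    top = tetramer.dimer_top
    centroid = top.positions.mean(axis=0)
    rot = _rot_z(twist)
    moved = top.transformed(translation=-centroid)
    moved = moved.transformed(rotation=rot, translation=centroid)
    return moved.transformed(translation=[dx, dy, dz])


def refine_tetramer(
    tetramer: TransTetramer,
    gap_bounds=(-1.0, 3.0),
    lateral_bounds=(-3.0, 3.0),
    twist_bounds=(-15.0, 15.0),
    params: EnergyParams = None,
) -> TransTetramer:
    """Deterministic local rigid-body refinement of the flipped dimer.

    Nelder-Mead over (dz, dx, dy, twist) from the symmetric start with a
    fixed initial simplex; overlapping or out-of-bounds poses are penalized
    so the returned energy never exceeds the input energy.
    """
    params = params or tetramer.params
    bounds = np.array([gap_bounds, lateral_bounds, lateral_bounds, twist_bounds])
    if not np.all(np.isfinite(bounds)):
        raise ValueError("refinement bounds must be finite")

    bottom = tetramer.dimer_bottom

    def objective(x):
        if np.any(x < bounds[:, 0]) or np.any(x > bounds[:, 1]):
            return 1e9 + float(np.sum(np.abs(x)))
        top = _placed_top(tetramer, x)
        sep = _min_surface_separation(bottom, top)
        if sep < 0:
            return 1e6 - 1e3 * sep
        return pair_energy(
            bottom.positions, bottom.charges, top.positions, top.charges, params
        )[2]

    x0 = np.zeros(4)
    e0 = objective(x0)
    if e0 >= 1e6:
        raise AssemblyError("no feasible non-overlapping start for refinement")
    best_x, best_e = x0, e0
    # coarse descent then a polish restart with a shrunken simplex
    for steps in ([0.25, 0.25, 0.25, 5.0], [0.02, 0.02, 0.02, 0.5]):
        simplex = np.vstack([best_x] + [best_x + s * e for s, e in
                                        zip(steps, np.eye(4))])
        res = minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": 1e-6,
                "fatol": 1e-10,
                "maxiter": 4000,
            },
        )
        if res.fun < best_e:
            best_x, best_e = res.x, res.fun
    if best_e >= 1e6:
        raise AssemblyError("no feasible non-overlapping pose within bounds")
    top = _placed_top(tetramer, best_x)
    return TransTetramer(
        dimer_top=top,
        dimer_bottom=bottom,
        gap=tetramer.gap + float(best_x[0]),
        trans_mode=tetramer.trans_mode,
        params=params,
    )
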