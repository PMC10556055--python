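"""Rotational cis interaction-energy landscapes.

Two membrane-aligned monomers sit side by side in the same membrane.  Each is
rotated about its own axis by (theta1, theta2); the second monomer is then
brought in along +x until the minimal bead-surface separation equals a fixed
contact gap.  The non-bonded energy of every rotation pair forms a 2-D
landscape whose low-energy decile defines the stable cis dimer states, and
whose 270 +/- 10 degree window corresponds to the known pore-forming
orientation of claudin dimers.

The contact distance has a closed form: for each inter-model bead pair the
offset at which that pair reaches surface separation ``gap`` is
``dx + sqrt((gap + r_i + r_j)^2 - c^2)`` (c the in-plane yz offset), and the
contact distance is the maximum over pairs — at that offset the binding pair
sits exactly at the gap and every other pair is at least as far.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import COULOMB_CONSTANT, EnergyParams, pair_energy
from .structures import BeadModel

__all__ = [
    "Pose",
    "EnergyLandscape",
    "StableStates",
    "WindowStats",
    "place_at_contact",
    "interaction_energy",
    "compute_landscape",
    "stable_states",
    "window_stats",
]

DEFAULT_CONTACT_GAP = 0.5  # A


class PlacementError(ValueError):
    """No contact placement exists for the requested rotations."""


def _rot_z(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class Pose:
    """Relative placement of a side-by-side pair.

    Monomer A is rotated by ``theta1`` about its axis at the origin; monomer B
    is rotated by ``theta2`` and offset by ``center_distance`` along +x.
    """

    theta1: float
    theta2: float
    center_distance: float

    def __post_init__(self):
        if self.center_distance <= 0:
            raise ValueError("center_distance must be positive")

    def apply(self, model_a: BeadModel, model_b: BeadModel):
        a = model_a.transformed(rotation=_rot_z(self.theta1))
        b = model_b.transformed(
            rotation=_rot_z(self.theta2),
            translation=[self.center_distance, 0.0, 0.0],
        )
        return a, b


def contact_distance(pos_a, rad_a, pos_b, rad_b, contact_gap: float) -> float:
    """Offset of group B along +x at which the minimal surface separation
    equals ``contact_gap`` (exact closed form)."""
    dx = pos_a[:, 0][:, None] - pos_b[:, 0][None, :]
    c2 = (pos_a[:, 1][:, None] - pos_b[:, 1][None, :]) ** 2 + (
        pos_a[:, 2][:, None] - pos_b[:, 2][None, :]
    ) ** 2
    s = contact_gap + rad_a[:, None] + rad_b[None, :]
    feasible = c2 <= s**2
    if not np.any(feasible):
        raise PlacementError(
            "models never reach the contact gap along +x (no yz overlap)"
        )
    roots = np.where(feasible, dx + np.sqrt(np.maximum(s**2 - c2, 0.0)), -np.inf)
    return float(np.max(roots))


def place_at_contact(
    model_a: BeadModel,
    model_b: BeadModel,
    theta1: float,
    theta2: float,
    contact_gap: float = DEFAULT_CONTACT_GAP,
) -> Pose:
    """Rotate the monomers and slide B along +x to the contact gap."""
    a = model_a.positions @ _rot_z(theta1).T
    b = model_b.positions @ _rot_z(theta2).T
    d = contact_distance(a, model_a.radii, b, model_b.radii, contact_gap)
    if d <= 0:
        raise PlacementError("contact placement collapsed to non-positive distance")
    return Pose(theta1=theta1, theta2=theta2, center_distance=d)


def interaction_energy(
    model_a: BeadModel, model_b: BeadModel, pose: Pose, params: EnergyParams = None
):
    """(E_LJ, E_Coul, E_total) in kJ/mol for a posed pair."""
    a, b = pose.apply(model_a, model_b)
    return pair_energy(a.positions, a.charges, b.positions, b.charges, params)


@dataclass
class EnergyLandscape:
    """Complete grid of pair energies over (theta1, theta2)."""

    thetas: np.ndarray          # (nT,) degrees
    e_lj: np.ndarray            # (nT, nT) kJ/mol, rows theta1
    e_coul: np.ndarray
    e_total: np.ndarray
    center_distances: np.ndarray
    increment: float
    contact_gap: float
    params: EnergyParams
    labels: tuple = ("A", "B")

    @property
    def n_cells(self) -> int:
        return self.e_total.size

    def _index(self, theta: float) -> int:
        return int(round((theta % 360.0) / self.increment)) % len(self.thetas)

    def energy_at(self, theta1: float, theta2: float) -> float:
        """Total energy of the cell containing (theta1, theta2); periodic."""
        return float(self.e_total[self._index(theta1), self._index(theta2)])

    def min_cell(self):
        i, j = np.unravel_index(np.argmin(self.e_total), self.e_total.shape)
        return float(self.thetas[i]), float(self.thetas[j]), float(self.e_total[i, j])

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.e_total, index=self.thetas, columns=self.thetas)
        frame.index.name = "theta1_deg"
        frame.to_csv(path)

    def summary(self) -> dict:
        t1, t2, e = self.min_cell()
        ss = stable_states(self)
        ws = window_stats(self) if 360.0 % self.increment == 0 else None
        out = {
            "labels": list(self.labels),
            "increment_deg": self.increment,
            "n_cells": int(self.n_cells),
            "min_cell": {"theta1": t1, "theta2": t2, "e_total_kj_mol": e},
            "decile_threshold_kj_mol": ss.threshold,
            "stable_state_count": ss.count,
            "stable_state_mean_kj_mol": ss.mean,
            "stable_state_sd_kj_mol": ss.sd,
        }
        if ws is not None:
            out["pore_window"] = {
                "center_deg": 270.0,
                "halfwidth_deg": 10.0,
                "count": ws.count,
                "mean_kj_mol": ws.mean,
                "sd_kj_mol": ws.sd,
            }
        return out


def compute_landscape(
    model_a: BeadModel,
    model_b: BeadModel,
    increment: float = 1.0,
    params: EnergyParams = None,
    contact_gap: float = DEFAULT_CONTACT_GAP,
) -> EnergyLandscape:
    """Evaluate place-at-contact + pair energy on the full rotation grid.

    Vectorized over theta2 for each theta1; exact per-cell results match the
    scalar :func:`place_at_contact` / :func:`interaction_energy` path.
    """
    if not float(360.0 / increment).is_integer():
        raise ValueError("360 must be divisible by the rotation increment")
    params = params or EnergyParams()
    thetas = np.arange(0.0, 360.0, increment)
    n_t = len(thetas)

    pa0 = model_a.positions
    pb0 = model_b.positions
    rad_a, rad_b = model_a.radii, model_b.radii
    q_a, q_b = model_a.charges, model_b.charges

    # all rotations of B, shape (nT, m, 3)
    cos = np.cos(np.radians(thetas))[:, None]
    sin = np.sin(np.radians(thetas))[:, None]
    bx = pb0[:, 0][None, :] * cos - pb0[:, 1][None, :] * sin
    by = pb0[:, 0][None, :] * sin + pb0[:, 1][None, :] * cos
    bz = np.broadcast_to(pb0[:, 2][None, :], bx.shape)

    s = contact_gap + rad_a[:, None] + rad_b[None, :]  # (n, m)
    s2 = s**2
    qq = np.outer(q_a, q_b)
    has_charge = np.any(qq != 0.0)

    e_lj = np.empty((n_t, n_t))
    e_coul = np.empty((n_t, n_t))
    dists = np.empty((n_t, n_t))
    failures = []
    for i, t1 in enumerate(thetas):
        pa = pa0 @ _rot_z(t1).T  # (n, 3)
        dx = pa[:, 0][None, :, None] - bx[:, None, :]      # (nT, n, m)
        c2 = (pa[:, 1][None, :, None] - by[:, None, :]) ** 2 + (
            pa[:, 2][None, :, None] - bz[:, None, :]
        ) ** 2
        feasible = c2 <= s2[None, :, :]
        any_feasible = feasible.any(axis=(1, 2))
        roots = np.where(
            feasible, dx + np.sqrt(np.maximum(s2[None, :, :] - c2, 0.0)), -np.inf
        )
        d = roots.max(axis=(1, 2))  # (nT,)
        r2 = (dx - d[:, None, None]) ** 2 + c2
        r = np.sqrt(r2)
        within = r <= params.cutoff
        sr6 = np.where(within, (params.sigma**2 / r2) ** 3, 0.0)
        e_lj[i] = np.sum(4.0 * params.epsilon * (sr6**2 - sr6), axis=(1, 2))
        if has_charge:
            inv_r = np.where(within, 1.0 / r, 0.0)
            e_coul[i] = (COULOMB_CONSTANT / params.eps_r) * np.sum(
                qq[None, :, :] * inv_r * 10.0, axis=(1, 2)
            )
        else:
            e_coul[i] = 0.0
        dists[i] = d
        if not np.all(any_feasible):
            for j in np.nonzero(~any_feasible)[0]:
                failures.append((float(t1), float(thetas[j])))
    if failures:
        raise PlacementError(
            f"contact placement failed at grid cells {failures[:5]}"
            + ("..." if len(failures) > 5 else "")
        )
    return EnergyLandscape(
        thetas=thetas,
        e_lj=e_lj,
        e_coul=e_coul,
        e_total=e_lj + e_coul,
        center_distances=dists,
        increment=float(increment),
        contact_gap=contact_gap,
        params=params,
        labels=(model_a.label or "A", model_b.label or "B"),
    )


@dataclass(frozen=True)
class StableStates:
    """Low-energy decile (or other percentile) of a landscape."""

    states: np.ndarray   # (k, 3): theta1, theta2, energy; ascending energy
    threshold: float     # energy of the last included state
    mean: float
    sd: float
    count: int


def stable_states(landscape: EnergyLandscape, percentile: float = 10.0) -> StableStates:
    """Cells below the rank-based percentile of the energy distribution.

    The count is exactly ``floor(percentile/100 * n_cells)``; ties are broken
    by (theta1, theta2) lexicographic order so the count stays integer-exact.
    """
    if landscape.n_cells == 0:
        raise ValueError("empty landscape")
    n = landscape.n_cells
    k = int(math.floor(percentile / 100.0 * n))
    t1 = np.repeat(landscape.thetas, len(landscape.thetas))
    t2 = np.tile(landscape.thetas, len(landscape.thetas))
    e = landscape.e_total.ravel()
    order = np.lexsort((t2, t1, e))
    sel = order[:k]
    states = np.column_stack([t1[sel], t2[sel], e[sel]])
    if k == 0:
        return StableStates(states=states, threshold=float("nan"),
                            mean=float("nan"), sd=float("nan"), count=0)
    energies = states[:, 2]
    sd = float(np.std(energies, ddof=1)) if k > 1 else 0.0
    return StableStates(
        states=states,
        threshold=float(energies[-1]),
        mean=float(np.mean(energies)),
        sd=sd,
        count=k,
    )


@dataclass(frozen=True)
class WindowStats:
    mean: float
    sd: float
    count: int
    cells: np.ndarray  # (k, 2) theta1, theta2


def window_stats(
    landscape: EnergyLandscape,
    center: float = 270.0,
    halfwidth: float = 10.0,
    closed: bool = False,
) -> WindowStats:
    """Energy statistics over the pore-forming rotational window.

    Both angles must lie in the periodic window around ``center``; the window
    is half-open ``[center - halfwidth, center + halfwidth)`` by default
    (20 x 20 = 400 cells on a 1 degree grid), or closed (21 x 21) with
    ``closed=True``.
    """
    if halfwidth >= 180.0:
        raise ValueError("halfwidth must be below 180 degrees")
    offset = (landscape.thetas - (center - halfwidth)) % 360.0
    if closed:
        axis_mask = offset <= 2.0 * halfwidth
    else:
        axis_mask = offset < 2.0 * halfwidth
    cell_mask = np.outer(axis_mask, axis_mask)
    energies = landscape.e_total[cell_mask]
    t1 = np.repeat(landscape.thetas, len(landscape.thetas))
    t2 = np.tile(landscape.thetas, len(landscape.thetas))
    cells = np.column_stack([t1[cell_mask.ravel()], t2[cell_mask.ravel()]])
    count = int(energies.size)
    sd = float(np.std(energies, ddof=1)) if count > 1 else 0.0
    mean = float(np.mean(energies)) if count else float("nan")
    return WindowStats(mean=mean, sd=sd, count=count, cells=cells)
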