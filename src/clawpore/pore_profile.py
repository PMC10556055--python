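"""Channel profiling by maximal inscribed probe spheres.

The paracellular channel of an assembled tetramer runs along z.  For each z
slice the profiler finds the in-plane point maximizing the clearance

    c(p) = min_i ( |p - b_i| - radius_i )

over all beads (3-D distances), seeded from the previous slice's centre so
the centre path is chained through the channel, HOLE-style.  The probe
radius of a slice is max(c, 0); twice the smallest probe radius is the
minimum pore diameter.  A slice whose centre jumps more than twice the z
step laterally breaks the tunnel; broken or sub-threshold channels are
reported as diameter 0 with ``pore_exists`` false rather than omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .structures import BeadModel

__all__ = ["PoreProfile", "profile_pore", "min_diameter_report"]

DEFAULT_Z_STEP = 0.5          # A
DEFAULT_PROBE_THRESHOLD = 0.9  # A, common minimum tunnel probe


@dataclass
class PoreProfile:
    z: np.ndarray              # (k,) A, ascending
    centers: np.ndarray        # (k, 2) in-plane centre of the maximal probe
    probe_radius: np.ndarray   # (k,) A, >= 0
    z_step: float
    probe_threshold: float
    broken: bool = False

    @property
    def min_diameter(self) -> float:
        if self.broken:
            return 0.0
        return float(max(2.0 * np.min(self.probe_radius), 0.0))

    @property
    def pore_exists(self) -> bool:
        return (not self.broken) and bool(
            np.all(self.probe_radius >= self.probe_threshold)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z,
                "cx": self.centers[:, 0],
                "cy": self.centers[:, 1],
                "radius": self.probe_radius,
                "diameter": 2.0 * self.probe_radius,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        dmin, z_at = min_diameter_report(self)
        return {
            "z_step": self.z_step,
            "probe_threshold": self.probe_threshold,
            "n_slices": int(len(self.z)),
            "min_diameter": dmin,
            "z_at_min_diameter": z_at,
            "pore_exists": self.pore_exists,
            "broken": self.broken,
        }


def _clearance(p_xy, z, positions, radii):
    d = np.sqrt(
        (positions[:, 0] - p_xy[0]) ** 2
        + (positions[:, 1] - p_xy[1]) ** 2
        + (positions[:, 2] - z) ** 2
    )
    return float(np.min(d - radii))


def _maximize_clearance(seed_xy, z, positions, radii, axis_xy, bound):
    # soft wall at `bound` from the structure axis keeps the maximization
    # inside the channel on open (non-enclosed) slices
    def objective(p):
        off = float(np.hypot(p[0] - axis_xy[0], p[1] - axis_xy[1]))
        penalty = max(0.0, off - bound) ** 2
        return -_clearance(p, z, positions, radii) + penalty

    best = None
    for start in seed_xy:
        res = minimize(
            objective,
            np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 800},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, _clearance(best.x, z, positions, radii)


def profile_pore(
    structure,
    z_range=None,
    z_step: float = DEFAULT_Z_STEP,
    probe_threshold: float = DEFAULT_PROBE_THRESHOLD,
    seed_center=None,
) -> PoreProfile:
    """Profile the channel of a bead model (or trans tetramer) along z.

    ``z_range`` defaults to the structure's z extent; the first slice is
    seeded at the structure axis (bead centroid in xy) unless
    ``seed_center`` is given.
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    if hasattr(structure, "combined_model"):  # TransTetramer
        model = structure.combined_model()
    else:
        model = structure
    if not isinstance(model, BeadModel):
        raise TypeError("structure must be a BeadModel or TransTetramer")
    positions, radii = model.positions, model.radii

    z_lo_struct = float(positions[:, 2].min())
    z_hi_struct = float(positions[:, 2].max())
    if z_range is None:
        z_lo, z_hi = z_lo_struct, z_hi_struct
    else:
        z_lo, z_hi = float(z_range[0]), float(z_range[1])
        if z_hi < z_lo_struct or z_lo > z_hi_struct:
            raise ValueError("z_range lies outside the structure extent")
    zs = np.arange(z_lo, z_hi + 0.5 * z_step, z_step)

    axis_xy = positions[:, :2].mean(axis=0)
    lateral = np.hypot(positions[:, 0] - axis_xy[0], positions[:, 1] - axis_xy[1])
    bound = float(lateral.max() + radii.max())
    prev = np.asarray(seed_center, dtype=float) if seed_center is not None else axis_xy

    centers = np.empty((len(zs), 2))
    probe = np.empty(len(zs))
    broken = False
    for k, z in enumerate(zs):
        # local slice centroid as a restart seed
        near = np.abs(positions[:, 2] - z) <= max(4.0 * z_step, 2.0)
        local = positions[near, :2].mean(axis=0) if near.any() else axis_xy
        center, clearance = _maximize_clearance(
            [prev, local], z, positions, radii, axis_xy, bound
        )
        centers[k] = center
        probe[k] = max(clearance, 0.0)
        if k > 0 and np.linalg.norm(center - centers[k - 1]) > 2.0 * z_step:
            broken = True
        prev = center
    return PoreProfile(
        z=zs,
        centers=centers,
        probe_radius=probe,
        z_step=z_step,
        probe_threshold=probe_threshold,
        broken=broken,
    )


def min_diameter_report(profile: PoreProfile, region=None):
    """(minimum diameter in A, z at the minimum); ties go to the smallest z.

    ``region`` optionally restricts to a z sub-interval.
    """
    if len(profile.z) == 0:
        raise ValueError("empty profile")
    if region is None:
        mask = np.ones(len(profile.z), dtype=bool)
    else:
        mask = (profile.z >= region[0]) & (profile.z <= region[1])
        if not mask.any():
            raise ValueError("region disjoint from profiled samples")
    radii = profile.probe_radius[mask]
    zs = profile.z[mask]
    if profile.broken:
        return 0.0, float(zs[0])
    k = int(np.argmin(radii))  # argmin returns the first (smallest z) tie
    return float(max(2.0 * radii[k], 0.0)), float(zs[k])
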