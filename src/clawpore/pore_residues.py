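"""Pore-lining residue identification and charge tallies.

A residue lines the pore when its bead lies within a cutoff (6 A by
default) of the channel.  Distance is measured to the channel *surface* by
default: the distance to the nearest centre-line sample minus that sample's
probe radius (a pure centre-line mode is selectable).  Members are
classified as positive (LYS, ARG), negative (ASP, GLU), polar (ASN, GLN,
SER, THR, TYR) or apolar, and tallied overall and by pore region — the two
mouths and the centre, split at z-thirds of the profiled interval.  The net
charge of the pore is the signed sum over members, i.e. the number of
positive minus the number of negative members.

Blocked or broken channels are refused with an explicit error rather than
an empty report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pore_profile import PoreProfile
from .structures import residue_charge_class

__all__ = ["PoreLiningReport", "PoreMember", "classify_residue", "pore_lining_report"]

DEFAULT_CUTOFF = 6.0  # A

CHARGE_CLASSES = ("positive", "negative", "polar", "apolar")
REGIONS = ("mouth_bottom", "center", "mouth_top")


class NoPoreError(ValueError):
    """The profile has no connected open channel; lining is not evaluated."""


def classify_residue(residue_name: str) -> str:
    """Charge class of a standard residue (positive/negative/polar/apolar)."""
    return residue_charge_class(residue_name)


@dataclass(frozen=True)
class PoreMember:
    bead_index: int
    residue_index: int
    residue_name: str
    chain_id: str
    charge: int
    charge_class: str
    distance: float  # A to the channel (surface by default)
    region: str


@dataclass
class PoreLiningReport:
    members: list
    cutoff: float
    mode: str  # "surface" or "centerline"

    @property
    def counts(self) -> dict:
        out = {c: 0 for c in CHARGE_CLASSES}
        for m in self.members:
            out[m.charge_class] += 1
        return out

    @property
    def net_charge(self) -> int:
        return int(sum(m.charge for m in self.members))

    def region_counts(self) -> dict:
        out = {r: {c: 0 for c in CHARGE_CLASSES} for r in REGIONS}
        for m in self.members:
            out[m.region][m.charge_class] += 1
        return out

    def region_net_charges(self) -> dict:
        out = {r: 0 for r in REGIONS}
        for m in self.members:
            out[m.region] += m.charge
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bead_index": m.bead_index,
                    "residue_index": m.residue_index,
                    "residue_name": m.residue_name,
                    "chain": m.chain_id,
                    "charge": m.charge,
                    "class": m.charge_class,
                    "distance": m.distance,
                    "region": m.region,
                }
                for m in self.members
            ]
        )

    def summary(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "mode": self.mode,
            "n_members": len(self.members),
            "counts": self.counts,
            "net_charge": self.net_charge,
            "region_counts": self.region_counts(),
            "region_net_charges": self.region_net_charges(),
        }


def _channel_distances(positions: np.ndarray, profile: PoreProfile, mode: str):
    """Distance of each bead to the channel and the z of its nearest sample."""
    samples = np.column_stack([profile.centers, profile.z])  # (k, 3) x, y, z
    diff = positions[:, None, :] - samples[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))  # (n, k)
    if mode == "surface":
        d = d - profile.probe_radius[None, :]
    elif mode != "centerline":
        raise ValueError("mode must be 'surface' or 'centerline'")
    nearest = np.argmin(d, axis=1)
    return d[np.arange(len(positions)), nearest], profile.z[nearest]


def _regions(z_nearest: np.ndarray, profile: PoreProfile) -> list:
    z_lo, z_hi = float(profile.z[0]), float(profile.z[-1])
    third = (z_hi - z_lo) / 3.0
    out = []
    for z in z_nearest:
        if z < z_lo + third:
            out.append("mouth_bottom")
        elif z < z_lo + 2.0 * third:
            out.append("center")
        else:
            out.append("mouth_top")
    return out


def pore_lining_report(
    structure,
    profile: PoreProfile,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "surface",
) -> PoreLiningReport:
    """Identify, classify and tally the residues lining a profiled channel."""
    if not profile.pore_exists:
        raise NoPoreError(
            "no connected open pore in the profile; lining residues are not "
            "evaluated in the absence of a pore structure"
        )
    if hasattr(structure, "combined_model"):
        model = structure.combined_model()
    else:
        model = structure
    dist, z_near = _channel_distances(model.positions, profile, mode)
    regions = _regions(z_near, profile)
    members = []
    for i in np.nonzero(dist <= cutoff)[0]:
        name = model.residue_names[i]
        members.append(
            PoreMember(
                bead_index=int(i),
                residue_index=int(model.residue_indices[i]),
                residue_name=name,
                chain_id=model.chain_ids[i],
                charge=int(model.charges[i]),
                charge_class=residue_charge_class(name),
                distance=float(dist[i]),
                region=regions[i],
            )
        )
    return PoreLiningReport(members=members, cutoff=cutoff, mode=mode)
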