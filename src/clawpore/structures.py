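"""Residue-level bead models of membrane proteins.

A protein is reduced to one bead per residue, placed at the side-chain
heavy-atom centroid (the C-alpha for glycine).  Each bead carries an integer
charge at pH 7.4 and a charge class used throughout the pore analysis:

* positive: LYS, ARG (+1)
* negative: ASP, GLU (-1)
* polar:    ASN, GLN, SER, THR, TYR (0)
* apolar:   everything else, including HIS (0)

Coordinates are in Angstrom, right-handed, with the membrane normal along +z.
Residue indices are 1-based as in PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "ResidueBead",
    "BeadModel",
    "MembraneFrame",
    "STANDARD_RESIDUES",
    "POLAR_RESIDUES",
    "DEFAULT_BEAD_RADIUS",
    "residue_charge",
    "load_structure",
    "truncate_cterm",
    "align_to_membrane_frame",
    "write_pdb",
    "write_csv",
]

#: The 20 standard amino acids (3-letter codes).
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

POSITIVE_RESIDUES = frozenset({"LYS", "ARG"})
NEGATIVE_RESIDUES = frozenset({"ASP", "GLU"})
POLAR_RESIDUES = frozenset({"ASN", "GLN", "SER", "THR", "TYR"})

#: Generic bead radius in Angstrom (half of a 5.28 A coarse-grained bead
#: diameter); overridable per call.
DEFAULT_BEAD_RADIUS = 2.64

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

SEGMENT_NAMES = ("TM1", "TM2", "TM3", "TM4", "ECS1", "ECS2", "loop", "cterm")


class StructureError(ValueError):
    """Raised for unreadable files, unknown residues, or degenerate geometry."""


def residue_charge(residue_name: str) -> int:
    """Integer charge of a standard residue at pH 7.4."""
    name = residue_name.upper()
    if name not in STANDARD_RESIDUES:
        raise StructureError(f"unknown residue name: {residue_name!r}")
    if name in POSITIVE_RESIDUES:
        return 1
    if name in NEGATIVE_RESIDUES:
        return -1
    return 0


def residue_charge_class(residue_name: str) -> str:
    """Charge class (positive / negative / polar / apolar) of a residue."""
    name = residue_name.upper()
    if name not in STANDARD_RESIDUES:
        raise StructureError(f"unknown residue name: {residue_name!r}")
    if name in POSITIVE_RESIDUES:
        return "positive"
    if name in NEGATIVE_RESIDUES:
        return "negative"
    if name in POLAR_RESIDUES:
        return "polar"
    return "apolar"


@dataclass(frozen=True)
class ResidueBead:
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # (3,) Angstrom
    radius: float
    charge: int
    charge_class: str


@dataclass(frozen=True)
class MembraneFrame:
    """Slab bounds of the membrane along the +z normal."""

    z_min: float = -15.0
    z_max: float = 15.0

    def __post_init__(self):
        if not self.z_min < self.z_max:
            raise ValueError("membrane frame requires z_min < z_max")

    @property
    def thickness(self) -> float:
        return self.z_max - self.z_min


@dataclass
class BeadModel:
    """One-bead-per-residue rigid model with charges and segment labels."""

    residue_indices: np.ndarray  # (N,) int
    residue_names: list
    chain_ids: list
    positions: np.ndarray  # (N, 3) float, Angstrom
    radii: np.ndarray  # (N,) float
    charges: np.ndarray  # (N,) int
    segments: dict = field(default_factory=dict)  # residue_index -> segment
    principal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    label: str = ""

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.principal_axis = np.asarray(self.principal_axis, dtype=float)
        if len(self) < 1:
            raise StructureError("a bead model needs at least one bead")
        if self.positions.shape != (len(self), 3):
            raise StructureError("positions must be (N, 3)")
        if np.any(self.radii <= 0):
            raise StructureError("bead radii must be positive")
        norm = np.linalg.norm(self.principal_axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise StructureError("principal axis must have unit norm")

    def __len__(self) -> int:
        return self.residue_indices.shape[0]

    @property
    def beads(self) -> list:
        return [
            ResidueBead(
                residue_index=int(self.residue_indices[i]),
                residue_name=self.residue_names[i],
                chain_id=self.chain_ids[i],
                position=self.positions[i].copy(),
                radius=float(self.radii[i]),
                charge=int(self.charges[i]),
                charge_class=residue_charge_class(self.residue_names[i]),
            )
            for i in range(len(self))
        ]

    @property
    def charge_classes(self) -> list:
        return [residue_charge_class(n) for n in self.residue_names]

    def net_charge(self) -> int:
        return int(round(float(np.sum(self.charges))))

    def segment_of(self, residue_index: int) -> str:
        return self.segments.get(int(residue_index), "loop")

    def segment_mask(self, prefix: str) -> np.ndarray:
        """Boolean mask of beads whose segment name starts with *prefix*."""
        return np.array(
            [self.segment_of(i).startswith(prefix) for i in self.residue_indices]
        )

    def copy(self) -> "BeadModel":
        return BeadModel(
            residue_indices=self.residue_indices.copy(),
            residue_names=list(self.residue_names),
            chain_ids=list(self.chain_ids),
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            charges=self.charges.copy(),
            segments=dict(self.segments),
            principal_axis=self.principal_axis.copy(),
            label=self.label,
        )

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "BeadModel":
        """Rigidly transformed copy: p -> R @ p + t."""
        out = self.copy()
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            out.positions = out.positions @ rotation.T
            out.principal_axis = rotation @ out.principal_axis
        if translation is not None:
            out.positions = out.positions + np.asarray(translation, dtype=float)
        return out

    def pairwise_distances(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))


def _sidechain_centroid(residue) -> np.ndarray:
    side = [
        a.get_coord()
        for a in residue.get_atoms()
        if a.element != "H" and a.get_name() not in _BACKBONE_ATOMS
    ]
    if side:
        return np.mean(np.asarray(side, dtype=float), axis=0)
    if "CA" in residue:
        return np.asarray(residue["CA"].get_coord(), dtype=float)
    # fall back to whatever heavy atoms exist (single-atom entries)
    atoms = [a.get_coord() for a in residue.get_atoms() if a.element != "H"]
    if not atoms:
        raise StructureError(
            f"residue {residue.get_resname()} {residue.get_id()[1]} has no heavy atoms"
        )
    return np.mean(np.asarray(atoms, dtype=float), axis=0)


def load_structure(path, chain: str = None, bead_radius: float = DEFAULT_BEAD_RADIUS,
                   radius_table: dict = None, label: str = None) -> BeadModel:
    """Read a PDB file into a one-bead-per-residue model.

    Bead positions are side-chain heavy-atom centroids (C-alpha for glycine);
    HETATM records are ignored.  ``radius_table`` maps residue names to bead
    radii and overrides the generic ``bead_radius``.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"could not parse PDB file {path}: {exc}") from exc

    model = next(structure.get_models(), None)
    if model is None:
        raise StructureError(f"no models in PDB file {path}")

    chains = [c for c in model.get_chains() if chain is None or c.get_id() == chain]
    if chain is not None and not chains:
        raise StructureError(f"chain {chain!r} not present in {path}")

    indices, names, chain_ids, positions = [], [], [], []
    for ch in chains:
        for residue in ch.get_residues():
            hetflag, resseq, _ = residue.get_id()
            if hetflag.strip():
                continue  # skip HETATM
            name = residue.get_resname().upper()
            if name not in STANDARD_RESIDUES:
                raise StructureError(
                    f"unknown residue name {name!r} at {ch.get_id()}:{resseq}"
                )
            indices.append(int(resseq))
            names.append(name)
            chain_ids.append(ch.get_id())
            positions.append(_sidechain_centroid(residue))
    if not indices:
        raise StructureError(f"no standard residues found in {path}" +
                             (f" (chain {chain!r})" if chain else ""))

    radii = np.array(
        [(radius_table or {}).get(n, bead_radius) for n in names], dtype=float
    )
    charges = np.array([residue_charge(n) for n in names], dtype=float)
    return BeadModel(
        residue_indices=np.array(indices),
        residue_names=names,
        chain_ids=chain_ids,
        positions=np.array(positions),
        radii=radii,
        charges=charges,
        segments={},
        label=label or str(path),
    )


def truncate_cterm(model: BeadModel, boundary: int) -> BeadModel:
    """Drop all residues with index greater than *boundary* (the cytosolic tail)."""
    idx = model.residue_indices
    if boundary < idx.min() or boundary > idx.max():
        raise StructureError(
            f"truncation boundary {boundary} outside residue range "
            f"[{idx.min()}, {idx.max()}]"
        )
    keep = idx <= boundary
    return BeadModel(
        residue_indices=idx[keep],
        residue_names=[n for n, k in zip(model.residue_names, keep) if k],
        chain_ids=[c for c, k in zip(model.chain_ids, keep) if k],
        positions=model.positions[keep],
        radii=model.radii[keep],
        charges=model.charges[keep],
        segments={i: s for i, s in model.segments.items() if i <= boundary},
        principal_axis=model.principal_axis.copy(),
        label=model.label,
    )


def _principal_rotation(points: np.ndarray) -> np.ndarray:
    """Rotation sending the largest-variance direction of *points* to +z."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] < 1e-8 * max(evals[2], 1.0):
        raise StructureError("degenerate (collinear) point set; cannot orient")
    axis = evecs[:, 2]
    e1 = evecs[:, 1]
    e0 = evecs[:, 0]
    # deterministic signs: largest-magnitude component positive
    for v in (axis, e1):
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1
    rot = np.vstack([e1, np.cross(axis, e1), axis])  # rows -> new x, y, z
    if np.linalg.det(rot) < 0:  # keep right-handed
        rot[1] *= -1
    return rot


def align_to_membrane_frame(model: BeadModel) -> BeadModel:
    """Rigidly move the model so its TM principal axis is +z, TM centroid at origin.

    Uses the TM-segment beads when segment labels are present, otherwise all
    beads.  Pairwise distances are preserved exactly (pure rotation +
    translation).
    """
    if len(model) < 4:
        raise StructureError("need at least 4 beads to orient a model")
    tm_mask = model.segment_mask("TM")
    pts = model.positions[tm_mask] if tm_mask.sum() >= 4 else model.positions
    span = pts.max(axis=0) - pts.min(axis=0)
    if np.linalg.norm(span) <= 1.0:
        raise StructureError("beads span less than 1 A; cannot orient")
    rot = _principal_rotation(pts)
    centroid = pts.mean(axis=0)
    out = model.transformed(rotation=rot, translation=-rot @ centroid)
    # point the extracellular side (ECS beads if labelled) to +z
    ecs_mask = out.segment_mask("ECS")
    if ecs_mask.any() and out.positions[ecs_mask, 2].mean() < 0:
        flip = np.diag([1.0, -1.0, -1.0])  # proper rotation about x
        out = out.transformed(rotation=flip)
    out.principal_axis = np.array([0.0, 0.0, 1.0])
    return out


# ---------------------------------------------------------------------------
# serialization

def write_pdb(model: BeadModel, path) -> None:
    """Write one pseudo-atom (element C, occupancy 1.00) per bead."""
    with open(path, "w") as fh:
        serial = 0
        for i in range(len(model)):
            serial += 1
            x, y, z = model.positions[i]
            fh.write(
                "ATOM  {serial:5d}  CA  {res:<3s} {chain:1s}{idx:4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
                " C\n".format(
                    serial=serial,
                    res=model.residue_names[i],
                    chain=(model.chain_ids[i] or "A")[:1],
                    idx=int(model.residue_indices[i]),
                    x=x, y=y, z=z, occ=1.0, b=0.0,
                )
            )
        fh.write("END\n")


def write_csv(model: BeadModel, path) -> None:
    frame = pd.DataFrame(
        {
            "residue_index": model.residue_indices,
            "name": model.residue_names,
            "chain": model.chain_ids,
            "x": model.positions[:, 0],
            "y": model.positions[:, 1],
            "z": model.positions[:, 2],
            "radius": model.radii,
            "charge": model.charges.astype(int),
            "class": model.charge_classes,
            "segment": [model.segment_of(i) for i in model.residue_indices],
        }
    )
    frame.to_csv(path, index=False)
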