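"""Rigid-body molecule representation, file readers and pose transforms.

A :class:`Molecule` stores per-atom element symbols and body-frame
Cartesian coordinates with the mass-weighted center of mass (COM) at the
origin.  Molecules are rigid: a :class:`Pose` carries the five degrees
of freedom per molecule used throughout the package — a COM translation
``(x, y, z)`` and two rotation angles ``(theta_x, theta_y)`` about the
body x- and y-axes.  Rotations are applied intrinsically, x first then
y, about axes through the COM, followed by the translation.

File input goes through RDKit (SDF V2000 and XYZ); a minimal
multi-molecule XYZ writer annotates each block with pose and energy
metadata so optimized bundles round-trip.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forcefield import ForceField, default_forcefield

__all__ = [
    "Molecule",
    "Pose",
    "POSITION_BOUND",
    "DegenerateGeometryError",
    "load_molecule",
    "normal_vector",
    "rotation_matrix",
    "apply_pose",
    "write_xyz_bundle",
    "read_xyz_bundle",
]

#: translational search bound, Angstrom (each of x, y, z in [-16, 16])
POSITION_BOUND = 16.0


class DegenerateGeometryError(ValueError):
    """Molecule geometry does not define the requested quantity."""


@dataclass(frozen=True)
class Pose:
    """Five rigid-body degrees of freedom of one molecule."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    theta_x: float = 0.0  # radians
    theta_y: float = 0.0  # radians

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.theta_x, self.theta_y])

    @classmethod
    def from_array(cls, v) -> "Pose":
        v = np.asarray(v, dtype=float)
        if v.shape != (5,):
            raise ValueError(f"pose vector must have shape (5,), got {v.shape}")
        return cls(*v)

    def validate(self) -> "Pose":
        if max(abs(self.x), abs(self.y), abs(self.z)) > POSITION_BOUND + 1e-12:
            raise ValueError(
                f"translation out of bounds [-{POSITION_BOUND}, {POSITION_BOUND}]: "
                f"({self.x}, {self.y}, {self.z})"
            )
        if max(abs(self.theta_x), abs(self.theta_y)) > math.pi + 1e-12:
            raise ValueError("rotation angles must lie in [-pi, pi]")
        return self


class Molecule:
    """Rigid molecule: elements, body-frame coordinates, per-atom masses.

    The constructor recenters the coordinates so the mass-weighted COM
    sits at the origin.
    """

    def __init__(self, name: str, elements, coords, masses=None,
                 forcefield: ForceField | None = None):
        elements = list(elements)
        coords = np.asarray(coords, dtype=float).reshape(len(elements), 3)
        if not elements:
            raise ValueError("molecule must contain at least one atom")
        if masses is None:
            ff = forcefield or default_forcefield()
            masses = ff.masses(elements)
        masses = np.asarray(masses, dtype=float)
        if masses.shape != (len(elements),) or np.any(masses <= 0):
            raise ValueError("masses must be positive, one per atom")
        com = masses @ coords / masses.sum()
        self.name = name
        self.elements = elements
        self.coords_body = coords - com
        self.masses = masses

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def center_of_mass(self) -> np.ndarray:
        """COM in the body frame — the origin by construction."""
        return self.masses @ self.coords_body / self.total_mass

    def distance_matrix(self) -> np.ndarray:
        d = self.coords_body[:, None, :] - self.coords_body[None, :, :]
        return np.sqrt((d**2).sum(-1))

    def __repr__(self) -> str:
        return f"Molecule({self.name!r}, {self.n_atoms} atoms)"


def _molecule_from_rdkit(mol, name: str, forcefield: ForceField | None) -> Molecule:
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
          conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
    )
    if np.allclose(coords[:, 2], 0.0) and mol.GetNumAtoms() > 3:
        warnings.warn(
            f"{name}: all z coordinates are zero; record may be a 2D depiction",
            stacklevel=3,
        )
    return Molecule(name, elements, coords, forcefield=forcefield)


def load_molecule(path: str | Path, fmt: str | None = None,
                  forcefield: ForceField | None = None) -> Molecule:
    """Read a molecule from an XYZ or SDF (V2000) file.

    Hydrogens are retained; coordinates are recentered to put the
    mass-weighted COM at the origin.  ``fmt`` defaults to the file
    extension.
    """
    from rdkit import Chem

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        mol = Chem.MolFromXYZFile(str(path))
        if mol is None or mol.GetNumAtoms() == 0:
            raise ValueError(f"could not parse XYZ file {path}")
    elif fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise ValueError(f"could not parse SDF/MOL file {path}")
    else:
        raise ValueError(f"unsupported molecule format {fmt!r}")
    return _molecule_from_rdkit(mol, name=path.stem, forcefield=forcefield)


def normal_vector(mol_or_coords, masses=None) -> np.ndarray:
    """Best-fit plane normal of a molecule (unit vector).

    Computed as the eigenvector of the smallest eigenvalue of the
    mass-weighted coordinate covariance about the COM; for a planar
    molecule this is the plane normal.  The sign is canonicalized so
    the first nonzero component is positive.
    """
    if isinstance(mol_or_coords, Molecule):
        coords = mol_or_coords.coords_body
        masses = mol_or_coords.masses
    else:
        coords = np.asarray(mol_or_coords, dtype=float)
        masses = np.ones(len(coords)) if masses is None else np.asarray(masses, float)
    if len(coords) < 3:
        raise DegenerateGeometryError("normal vector needs >= 3 atoms")
    com = masses @ coords / masses.sum()
    X = (coords - com) * np.sqrt(masses)[:, None]
    cov = X.T @ X / masses.sum()
    evals, evecs = np.linalg.eigh(cov)  # ascending
    # collinear molecules have two (near-)zero spreads -> no unique plane
    if evals[1] <= 1e-10 * max(evals[2], 1e-300):
        raise DegenerateGeometryError("atoms are collinear; plane normal undefined")
    n = evecs[:, 0]
    for comp in n:
        if abs(comp) > 1e-12:
            if comp < 0:
                n = -n
            break
    return n


def rotation_matrix(theta_x: float, theta_y: float) -> np.ndarray:
    """R = R_y(theta_y) @ R_x(theta_x)."""
    cx, sx = math.cos(theta_x), math.sin(theta_x)
    cy, sy = math.cos(theta_y), math.sin(theta_y)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return ry @ rx


def apply_pose(mol: Molecule, pose: Pose) -> np.ndarray:
    """World-frame coordinates of ``mol`` under ``pose``.

    The COM of the result equals ``(pose.x, pose.y, pose.z)``.
    """
    pose.validate()
    R = rotation_matrix(pose.theta_x, pose.theta_y)
    return mol.coords_body @ R.T + np.array([pose.x, pose.y, pose.z])


# ---------------------------------------------------------------------------
# multi-molecule XYZ bundle with metadata comment lines

def write_xyz_bundle(path: str | Path, molecules, poses, comments=None) -> None:
    """Write molecules at their posed world coordinates as concatenated XYZ.

    Each block's comment line records the molecule name, the pose, and
    any extra per-molecule comment (e.g. an energy) so a bundle is
    self-describing.
    """
    path = Path(path)
    lines = []
    comments = comments or [""] * len(molecules)
    for mol, pose, extra in zip(molecules, poses, comments):
        world = apply_pose(mol, pose)
        meta = (
            f"name={mol.name} pose={pose.x:.10g},{pose.y:.10g},{pose.z:.10g},"
            f"{pose.theta_x:.10g},{pose.theta_y:.10g}"
        )
        if extra:
            meta += f" {extra}"
        lines.append(str(mol.n_atoms))
        lines.append(meta)
        for el, xyz in zip(mol.elements, world):
            lines.append(f"{el} {xyz[0]: .10f} {xyz[1]: .10f} {xyz[2]: .10f}")
    path.write_text("\n".join(lines) + "\n")


def read_xyz_bundle(path: str | Path):
    """Read a bundle written by :func:`write_xyz_bundle`.

    Returns a list of ``(name, elements, world_coords, pose_or_None)``.
    """
    blocks = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        meta = lines[i + 1]
        name, pose = "molecule", None
        for tok in meta.split():
            if tok.startswith("name="):
                name = tok[5:]
            elif tok.startswith("pose="):
                pose = Pose(*(float(v) for v in tok[5:].split(",")))
        elements, coords = [], []
        for rec in lines[i + 2 : i + 2 + n]:
            f = rec.split()
            elements.append(f[0])
            coords.append([float(f[1]), float(f[2]), float(f[3])])
        blocks.append((name, elements, np.array(coords), pose))
        i += 2 + n
    return blocks
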