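"""Total energy of n rigid molecules inside one tube.

The model is hybrid discrete-continuum: each drug atom interacts with
the tube wall through the closed-form atom-cylinder energy (continuum
wall), while drug-drug interactions are summed discretely over all
atom pairs with mixed Lennard-Jones parameters and no cutoff.  Systems
are small (<= a few hundred atoms), so exact double loops are used —
no neighbor lists, no periodicity.

During evolutionary optimization, configurations that push an atom onto
or past the wall receive a finite penalty energy ``1e6 * (1 + worst
violation in Angstrom)`` so the fitness stays defined everywhere; the
public :func:`total_energy` on a feasible configuration is always the
exact value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .continuum import TubeModel, WallDomainError, point_cylinder_energy
from .forcefield import ForceField
from .molecule import Molecule, Pose, apply_pose

__all__ = [
    "Configuration",
    "EnergyBreakdown",
    "molecule_tube_energy",
    "pairwise_drug_energy",
    "total_energy",
    "PopulationEvaluator",
    "WALL_MARGIN",
    "PENALTY_SCALE",
]

#: atoms must stay this far (Angstrom) inside the wall during optimization
WALL_MARGIN = 0.05
#: base magnitude of the wall-violation penalty, kcal/mol
PENALTY_SCALE = 1.0e6


@dataclass
class Configuration:
    """n molecules with their poses inside one tube.

    Round-trips to/from a flat decision vector of length ``5 n``:
    ``(x, y, z, theta_x, theta_y)`` per molecule.
    """

    molecules: list[Molecule]
    poses: list[Pose]
    tube: TubeModel

    def __post_init__(self):
        if len(self.molecules) != len(self.poses):
            raise ValueError("one pose per molecule required")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([p.as_array() for p in self.poses])

    @classmethod
    def from_vector(cls, x, molecules, tube: TubeModel) -> "Configuration":
        x = np.asarray(x, dtype=float)
        if x.shape != (5 * len(molecules),):
            raise ValueError(
                f"decision vector must have length {5 * len(molecules)}, got {x.shape}"
            )
        poses = [Pose.from_array(x[5 * i : 5 * i + 5]) for i in range(len(molecules))]
        return cls(list(molecules), poses, tube)

    def world_coords(self) -> list[np.ndarray]:
        return [apply_pose(m, p) for m, p in zip(self.molecules, self.poses)]


@dataclass
class EnergyBreakdown:
    """Per-molecule wall terms, per-pair drug-drug terms, and their sum."""

    drug_tube: list[float]
    drug_drug: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.drug_tube) + sum(self.drug_drug.values()))


def molecule_tube_energy(world_coords, elements, tube: TubeModel,
                         forcefield: ForceField) -> float:
    """Continuum wall energy of one molecule: sum of per-atom cylinder terms.

    Every atom must be strictly inside the tube; the element of each
    atom is mixed with the wall carbon.
    """
    world_coords = np.asarray(world_coords, dtype=float)
    delta = np.hypot(world_coords[:, 0], world_coords[:, 1])
    if np.any(delta >= tube.a):
        raise WallDomainError("atom on or outside the tube wall")
    e = 0.0
    for el in set(elements):
        idx = [i for i, s in enumerate(elements) if s == el]
        pair = forcefield.pair(el, "C")
        e += float(np.sum(point_cylinder_energy(pair, tube, delta[idx])))
    return e


def pairwise_drug_energy(coords_i, elements_i, coords_j, elements_j,
                         forcefield: ForceField) -> float:
    """Discrete LJ energy between two molecules: all atom pairs, no cutoff."""
    coords_i = np.asarray(coords_i, float)
    coords_j = np.asarray(coords_j, float)
    diff = coords_i[:, None, :] - coords_j[None, :, :]
    r2 = (diff**2).sum(-1)
    if np.any(r2 <= 0):
        raise ValueError("coincident atoms between molecules (rho = 0)")
    A = np.empty(r2.shape)
    B = np.empty(r2.shape)
    for a_idx, el_i in enumerate(elements_i):
        for b_idx, el_j in enumerate(elements_j):
            pp = forcefield.pair(el_i, el_j)
            A[a_idx, b_idx] = pp.A
            B[a_idx, b_idx] = pp.B
    inv6 = r2**-3
    return float(np.sum((-A + B * inv6) * inv6))


def total_energy(config: Configuration, forcefield: ForceField) -> EnergyBreakdown:
    """Exact energy breakdown of a configuration (kcal/mol)."""
    worlds = config.world_coords()
    drug_tube = [
        molecule_tube_energy(w, m.elements, config.tube, forcefield)
        for w, m in zip(worlds, config.molecules)
    ]
    drug_drug: dict[tuple[int, int], float] = {}
    for i in range(config.n_molecules):
        for j in range(i + 1, config.n_molecules):
            drug_drug[(i, j)] = pairwise_drug_energy(
                worlds[i], config.molecules[i].elements,
                worlds[j], config.molecules[j].elements, forcefield,
            )
    return EnergyBreakdown(drug_tube=drug_tube, drug_drug=drug_drug)


class PopulationEvaluator:
    """Vectorized objective for populations of decision vectors.

    Evaluates the exact model energy for a whole population at once
    (closed-form wall terms through the stabilized hypergeometric,
    discrete drug-drug double sums via broadcasting).  Wall-violating
    individuals receive the finite penalty described in the module
    docstring instead of an exception, so evolutionary search has a
    well-defined fitness everywhere in the box.
    """

    def __init__(self, molecules: list[Molecule], tube: TubeModel,
                 forcefield: ForceField):
        self.molecules = list(molecules)
        self.tube = tube
        self.forcefield = forcefield
        self.n_mol = len(molecules)
        self.n_var = 5 * self.n_mol
        # flattened per-atom wall constants (element mixed with wall carbon)
        coords, wallA, wallB, owner = [], [], [], []
        for mi, mol in enumerate(self.molecules):
            for el, xyz in zip(mol.elements, mol.coords_body):
                pp = forcefield.pair(el, "C")
                coords.append(xyz)
                wallA.append(pp.A)
                wallB.append(pp.B)
                owner.append(mi)
        self._body = np.asarray(coords)          # (n_atoms_total, 3)
        self._wallA = np.asarray(wallA)
        self._wallB = np.asarray(wallB)
        self._owner = np.asarray(owner)
        self._slices = [np.flatnonzero(self._owner == m) for m in range(self.n_mol)]
        # per-molecule-pair LJ constant matrices
        self._pairAB: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for i in range(self.n_mol):
            for j in range(i + 1, self.n_mol):
                ei, ej = self.molecules[i].elements, self.molecules[j].elements
                A = np.empty((len(ei), len(ej)))
                B = np.empty((len(ei), len(ej)))
                for ai, el_i in enumerate(ei):
                    for bj, el_j in enumerate(ej):
                        pp = forcefield.pair(el_i, el_j)
                        A[ai, bj] = pp.A
                        B[ai, bj] = pp.B
                self._pairAB[(i, j)] = (A, B)

    def _world(self, X: np.ndarray) -> list[np.ndarray]:
        """Posed coordinates per molecule, shape (pop, n_atoms_m, 3)."""
        pop = X.shape[0]
        worlds = []
        for m, mol in enumerate(self.molecules):
            x, y, z, thx, thy = (X[:, 5 * m + k] for k in range(5))
            cx, sx = np.cos(thx), np.sin(thx)
            cy, sy = np.cos(thy), np.sin(thy)
            R = np.empty((pop, 3, 3))
            # R_y(thy) @ R_x(thx)
            R[:, 0, 0] = cy
            R[:, 0, 1] = sy * sx
            R[:, 0, 2] = sy * cx
            R[:, 1, 0] = 0.0
            R[:, 1, 1] = cx
            R[:, 1, 2] = -sx
            R[:, 2, 0] = -sy
            R[:, 2, 1] = cy * sx
            R[:, 2, 2] = cy * cx
            w = np.einsum("pij,aj->pai", R, mol.coords_body)
            w += np.stack([x, y, z], axis=1)[:, None, :]
            worlds.append(w)
        return worlds

    def evaluate(self, X) -> np.ndarray:
        """Energies (kcal/mol) of a population ``X`` of shape (pop, 5n)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_var:
            raise ValueError(f"expected {self.n_var} decision variables, got {X.shape[1]}")
        a, eta = self.tube.a, self.tube.eta
        worlds = self._world(X)
        all_w = np.concatenate(worlds, axis=1)  # (pop, n_atoms_total, 3)
        delta = np.hypot(all_w[..., 0], all_w[..., 1])
        viol = delta - (a - WALL_MARGIN)
        worst = viol.max(axis=1)
        infeasible = worst >= 0.0
        # clamp so the closed form stays finite; infeasible rows overwritten below
        dcl = np.minimum(delta, a - WALL_MARGIN)
        m3, m6 = 2.5, 5.5
        w_arg = 4.0 * a * dcl / (a + dcl) ** 2
        f3 = special.hyp2f1(m3, 0.5, 1.0, w_arg)
        f6 = special.hyp2f1(m6, 0.5, 1.0, w_arg)
        pref = 2.0 * np.pi * a
        i3 = pref * special.beta(m3, 0.5) / (a + dcl) ** 5 * f3
        i6 = pref * special.beta(m6, 0.5) / (a + dcl) ** 11 * f6
        energy = eta * ((-self._wallA * i3 + self._wallB * i6).sum(axis=1))
        # discrete drug-drug terms
        for (i, j), (A, B) in self._pairAB.items():
            diff = worlds[i][:, :, None, :] - worlds[j][:, None, :, :]
            r2 = np.maximum((diff**2).sum(-1), 1e-8)
            inv6 = r2**-3
            energy += ((-A + B * inv6) * inv6).sum(axis=(1, 2))
        energy[infeasible] = PENALTY_SCALE * (1.0 + worst[infeasible])
        return energy

    def breakdown(self, x) -> EnergyBreakdown:
        """Exact breakdown of one decision vector (must be feasible)."""
        config = Configuration.from_vector(x, self.molecules, self.tube)
        return total_energy(config, self.forcefield)
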