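"""Geometric descriptors of an equilibrium configuration.

Four parameters characterize how molecules sit inside the tube:

- ``d``     — shortest distance from a molecule's center of mass to the
              tube wall, ``a - sqrt(x^2 + y^2)`` (Angstrom);
- ``omega`` — separation angle between two molecules, measured at the
              tube axis between their COM projections onto the
              cross-sectional plane (degrees, in [0, 180]);
- ``gamma`` — tilt angle between a molecule's plane normal and the
              radial direction at its COM, folded into [0, 90] degrees
              (the normal's sign is arbitrary);
- ``xi``    — axial offset between two COMs, ``|z_i - z_j|`` (Angstrom).

Pairwise descriptors are reported for consecutive molecules after
sorting by ascending COM z (ties broken by azimuth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .continuum import TubeModel
from .molecule import DegenerateGeometryError, normal_vector, rotation_matrix
from .system import Configuration

__all__ = [
    "DescriptorTable",
    "wall_distance",
    "separation_angle",
    "tilt_angle",
    "axial_offset",
    "describe",
]

#: COM projections closer than this to the axis make omega ill-conditioned
AXIS_EPS = 1e-6


@dataclass
class DescriptorTable:
    """Per-molecule and consecutive-pair descriptors of one configuration."""

    d: list[float]
    gamma: list[float]
    omega: list[float]
    xi: list[float]
    order: list[int]  # original molecule indices in reporting order
    flags: list[str] = field(default_factory=list)

    def validate(self, tube: TubeModel) -> None:
        for di in self.d:
            if not 0.0 <= di <= tube.a:
                raise ValueError(f"wall distance {di} outside [0, a]")
        for g in self.gamma:
            if math.isnan(g):  # no defined plane (e.g. a single-atom probe)
                continue
            if not 0.0 <= g <= 90.0 + 1e-9:
                raise ValueError(f"tilt angle {g} outside [0, 90]")
        for om in self.omega:
            if not 0.0 <= om <= 180.0 + 1e-9:
                raise ValueError(f"separation angle {om} outside [0, 180]")
        for x in self.xi:
            if x < 0:
                raise ValueError(f"axial offset {x} negative")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.d)
        rows = {}
        for i in range(n):
            rows[f"d_{i + 1}"] = self.d[i]
            rows[f"gamma_{i + 1}"] = self.gamma[i]
        for k in range(n - 1):
            rows[f"omega_{k + 1}{k + 2}"] = self.omega[k]
            rows[f"xi_{k + 1}{k + 2}"] = self.xi[k]
        return pd.DataFrame([rows])


def wall_distance(com, tube: TubeModel) -> float:
    """d = a - sqrt(x^2 + y^2); COM must lie inside the tube."""
    com = np.asarray(com, dtype=float)
    r = math.hypot(com[0], com[1])
    if r >= tube.a:
        raise ValueError(f"center of mass outside the tube (r={r:.4f} >= a={tube.a})")
    return tube.a - r

def separation_angle(com_i, com_j) -> tuple[float, bool]:
    """Angle (degrees) at the axis between two COM cross-section projections.

    Returns ``(omega, ill_conditioned)``; the flag is set when either
    projection lies within ``AXIS_EPS`` of the axis, where the angle is
    numerically meaningless (a molecule essentially on the axis).
    """
    pi_ = np.asarray(com_i, float)[:2]
    pj_ = np.asarray(com_j, float)[:2]
    ri, rj = np.linalg.norm(pi_), np.linalg.norm(pj_)
    ill = bool(ri < AXIS_EPS or rj < AXIS_EPS)
    if ri == 0.0 or rj == 0.0:
        return 0.0, True
    c = float(np.clip(pi_ @ pj_ / (ri * rj), -1.0, 1.0))
    return math.degrees(math.acos(c)), ill


def tilt_angle(normal, com) -> float:
    """Acute angle (degrees) between the molecular normal and the radial direction.

    For a COM within ``AXIS_EPS`` of the axis the radial direction is
    undefined and 0 is returned (on-axis convention).
    """
    com = np.asarray(com, float)
    r = math.hypot(com[0], com[1])
    if r < AXIS_EPS:
        return 0.0
    radial = np.array([com[0] / r, com[1] / r, 0.0])
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    c = float(np.clip(n @ radial, -1.0, 1.0))
    theta = math.degrees(math.acos(c))
    return min(theta, 180.0 - theta)


def axial_offset(com_i, com_j) -> float:
    """xi = |z_i - z_j| (Angstrom)."""
    return abs(float(com_i[2]) - float(com_j[2]))


def describe(config: Configuration) -> DescriptorTable:
    """Full descriptor table of a configuration.

    Molecules are reported in ascending COM z order (ties by azimuth);
    range invariants are checked before returning.
    """
    coms = [p.as_array()[:3] for p in config.poses]
    order = sorted(
        range(config.n_molecules),
        key=lambda i: (coms[i][2], math.atan2(coms[i][1], coms[i][0])),
    )
    d, gamma, flags = [], [], []
    for i in order:
        d.append(wall_distance(coms[i], config.tube))
        pose = config.poses[i]
        try:
            n_body = normal_vector(config.molecules[i])
        except DegenerateGeometryError:
            gamma.append(float("nan"))
            flags.append(f"gamma_{len(gamma)}: no defined molecular plane")
            continue
        n_world = rotation_matrix(pose.theta_x, pose.theta_y) @ n_body
        gamma.append(tilt_angle(n_world, coms[i]))
    omega, xi = [], []
    for k in range(len(order) - 1):
        i, j = order[k], order[k + 1]
        om, ill = separation_angle(coms[i], coms[j])
        omega.append(om)
        xi.append(axial_offset(coms[i], coms[j]))
        if ill:
            flags.append(f"omega_{k + 1}{k + 2}: on-axis projection, ill-conditioned")
    table = DescriptorTable(d=d, gamma=gamma, omega=omega, xi=xi, order=order, flags=flags)
    table.validate(config.tube)
    return table
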