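"""Closed-form Lennard-Jones energy between an atom and an infinite cylinder.

The nanotube wall is treated as a smooth cylinder of radius ``a`` with a
uniform atomic surface density ``eta`` (the graphene value, 0.3812
atoms/A^2, by default).  For an atom at perpendicular distance ``delta``
from the axis the surface integrals

    I_n = integral over the cylinder of rho^{-2n} dS,   n in {3, 6},

have the closed form

    I_n = 2*pi*a / (a - delta)^(2n-1) * B(n - 1/2, 1/2)
          * 2F1(n - 1/2, 1/2; 1; -4*a*delta / (a - delta)^2),

with B the beta function and 2F1 the Gauss hypergeometric function, and
the atom-wall energy is

    E_p(delta) = eta * (-A * I_3 + B * I_6).

The hypergeometric argument diverges to -inf as the atom approaches the
wall; we evaluate through the Pfaff transformation

    2F1(m, 1/2; 1; z) = (1 - z)^(-m) * 2F1(m, 1/2; 1; z/(z - 1)),

which maps the argument onto [0, 1) and keeps the evaluation stable for
delta/a arbitrarily close to 1 (validated against adaptive quadrature
in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .forcefield import PairParams

__all__ = ["TubeModel", "WallDomainError", "surface_integral", "point_cylinder_energy"]

#: mean atomic surface density of the CNT wall (graphene sheet), atoms/A^2
GRAPHENE_SURFACE_DENSITY = 0.3812


class WallDomainError(ValueError):
    """Atom placed on or outside the cylinder wall; only the interior is modeled."""


@dataclass(frozen=True)
class TubeModel:
    """Infinite cylinder: radius ``a`` (Angstrom), surface density ``eta``."""

    a: float
    eta: float = GRAPHENE_SURFACE_DENSITY

    def __post_init__(self):
        if not (self.a > 0 and self.eta > 0):
            raise ValueError(f"tube requires a > 0 and eta > 0 (a={self.a}, eta={self.eta})")


def surface_integral(a: float, delta, n: int):
    """The cylinder surface integral I_n (units A^(2-2n)).

    ``delta`` may be a scalar or array with ``0 <= delta < a``; values on
    or outside the wall raise :class:`WallDomainError`.
    """
    if n not in (3, 6):
        raise ValueError(f"n must be 3 or 6, got {n}")
    if a <= 0:
        raise ValueError("cylinder radius must be positive")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise WallDomainError("delta must be non-negative")
    if np.any(delta >= a):
        raise WallDomainError(f"atom on or outside the wall: delta >= a = {a}")
    # Pfaff-transformed closed form; argument 4*a*delta/(a+delta)^2 in [0, 1)
    m = n - 0.5
    w = 4.0 * a * delta / (a + delta) ** 2
    val = (
        2.0 * np.pi * a
        / (a + delta) ** (2 * n - 1)
        * special.beta(m, 0.5)
        * special.hyp2f1(m, 0.5, 1.0, w)
    )
    return float(val) if val.ndim == 0 else val


def point_cylinder_energy(pair: PairParams, tube: TubeModel, delta):
    """Atom-wall interaction energy E_p(delta) in kcal/mol.

    Diverges to +inf as ``delta -> a`` (the repulsive integral dominates).
    """
    i3 = surface_integral(tube.a, delta, 3)
    i6 = surface_integral(tube.a, delta, 6)
    return tube.eta * (-pair.A * i3 + pair.B * i6)
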