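"""Lennard-Jones force-field parameters and the 6-12 pair potential.

The interaction between two non-bonded atoms separated by a distance
``rho`` is the 6-12 Lennard-Jones potential

    Phi(rho) = -A / rho**6 + B / rho**12
             = eps * (-2 (sigma/rho)**6 + (sigma/rho)**12),

where ``eps`` is the well depth (kcal/mol) and ``sigma`` the van der
Waals diameter (Angstrom), i.e. the location of the minimum:
``Phi(sigma) = -eps``.  The attractive and repulsive constants are

    A = 2 * eps * sigma**6,      B = eps * sigma**12.

Unlike species are combined with the Lorentz-Berthelot mixing rules,
``eps_ij = sqrt(eps_i * eps_j)`` and ``sigma_ij = (sigma_i + sigma_j)/2``.
Per-element values ship as a plain-text UFF nonbonded table.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ElementParams",
    "PairParams",
    "ForceField",
    "MissingParameterError",
    "mix",
    "lj_potential",
    "default_forcefield",
]


class MissingParameterError(KeyError):
    """Raised when an element has no entry in the parameter table."""

    def __init__(self, element: str):
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # KeyError quotes its arg; be explicit
        return f"no Lennard-Jones parameters for element {self.element!r}"


@dataclass(frozen=True)
class ElementParams:
    """Per-element LJ well depth, vdW diameter and atomic mass."""

    element: str
    epsilon: float  # kcal/mol
    sigma: float  # Angstrom (distance at the potential minimum)
    mass: float  # amu

    def __post_init__(self):
        if not (self.epsilon > 0 and self.sigma > 0 and self.mass > 0):
            raise ValueError(
                f"parameters for {self.element!r} must be positive "
                f"(epsilon={self.epsilon}, sigma={self.sigma}, mass={self.mass})"
            )


@dataclass(frozen=True)
class PairParams:
    """Mixed LJ parameters for an element pair, with Eq-style A/B constants."""

    epsilon: float  # kcal/mol
    sigma: float  # Angstrom
    A: float  # attractive constant, kcal*A^6/mol
    B: float  # repulsive constant, kcal*A^12/mol

    @classmethod
    def from_eps_sigma(cls, epsilon: float, sigma: float) -> "PairParams":
        return cls(
            epsilon=epsilon,
            sigma=sigma,
            A=2.0 * epsilon * sigma**6,
            B=epsilon * sigma**12,
        )


def mix(params_i: ElementParams, params_j: ElementParams) -> PairParams:
    """Lorentz-Berthelot mixing: geometric-mean eps, arithmetic-mean sigma."""
    eps = math.sqrt(params_i.epsilon * params_j.epsilon)
    sig = 0.5 * (params_i.sigma + params_j.sigma)
    return PairParams.from_eps_sigma(eps, sig)


def lj_potential(pair: PairParams, rho):
    """Evaluate Phi(rho) = -A/rho^6 + B/rho^12 (kcal/mol); rho in Angstrom.

    ``rho`` may be a scalar or array; every entry must be positive.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("lj_potential requires rho > 0")
    inv6 = rho**-6
    out = (-pair.A + pair.B * inv6) * inv6
    return float(out) if out.ndim == 0 else out


class ForceField:
    """Element parameter table with cached pair mixing.

    Parameters are read from a plain-text file: one record per element
    (symbol, epsilon kcal/mol, sigma Angstrom, mass amu), ``#`` comments
    and blank lines allowed.
    """

    def __init__(self, elements: dict[str, ElementParams], source: str = "<dict>"):
        self._elements = dict(elements)
        self._pairs: dict[tuple[str, str], PairParams] = {}
        self.source = source

    @classmethod
    def from_file(cls, path: str | Path) -> "ForceField":
        path = Path(path)
        elements: dict[str, ElementParams] = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'element epsilon sigma mass', got {raw!r}"
                )
            sym = fields[0]
            eps, sig, mass = (float(x) for x in fields[1:])
            elements[sym] = ElementParams(sym, eps, sig, mass)
        return cls(elements, source=str(path))

    def __contains__(self, element: str) -> bool:
        return element in self._elements

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._elements)

    def element(self, symbol: str) -> ElementParams:
        try:
            return self._elements[symbol]
        except KeyError:
            raise MissingParameterError(symbol) from None

    def pair(self, element_i: str, element_j: str) -> PairParams:
        """Mixed parameters for an (unordered) element pair, cached."""
        key = (element_i, element_j) if element_i <= element_j else (element_j, element_i)
        try:
            return self._pairs[key]
        except KeyError:
            pp = mix(self.element(element_i), self.element(element_j))
            self._pairs[key] = pp
            return pp

    def masses(self, elements) -> np.ndarray:
        return np.array([self.element(e).mass for e in elements], dtype=float)

    def checksum(self) -> str:
        """SHA-256 over the sorted parameter records (logged per run)."""
        payload = "\n".join(
            f"{e.element} {e.epsilon!r} {e.sigma!r} {e.mass!r}"
            for e in sorted(self._elements.values(), key=lambda e: e.element)
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def default_forcefield() -> ForceField:
    """UFF nonbonded table bundled with the package."""
    with resources.as_file(
        resources.files("nanocap").joinpath("data/uff_nonbonded.txt")
    ) as p:
        return ForceField.from_file(p)
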