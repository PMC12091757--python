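"""Radius-landscape analysis: minimum energy as a function of tube radius.

For a fixed drug load the minimized encapsulation energy E_min(a) is
sampled on a grid of 10-15 tube radii, interpolated with a cubic
spline, and two landmarks are extracted:

- ``a0`` — the zero-energy radius, the smallest radius at which
  E_min(a) crosses zero from above: below it the tube cannot
  energetically accommodate the load;
- the optimal radii — interior stationary minima of the spline, global
  first.  At each reported minimum the system is re-optimized at that
  exact radius to produce the final configuration and energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .continuum import TubeModel
from .forcefield import ForceField, default_forcefield
from .molecule import Molecule
from .search import SearchResult, SearchSettings, optimize
from .system import PENALTY_SCALE

__all__ = ["LandscapeResult", "Minimum", "analyze_curve", "scan", "default_radius_grid"]


@dataclass
class Minimum:
    """One stationary minimum of the spline, with the re-optimized system."""

    a: float
    energy_spline: float
    energy: float  # re-optimized at this radius
    result: SearchResult


@dataclass
class LandscapeResult:
    radii: np.ndarray
    emin: np.ndarray
    spline: CubicSpline
    a0: float | None
    minima: list[Minimum]
    per_radius: list[SearchResult] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def curve(self, n_points: int = 200) -> np.ndarray:
        """(a, E) spline samples for plotting/CSV output."""
        a = np.linspace(self.radii[0], self.radii[-1], n_points)
        return np.column_stack([a, self.spline(a)])


def default_radius_grid(molecules, copies: int = 1, eta: float | None = None,
                        forcefield: ForceField | None = None,
                        n_radii: int = 12, span: float = 4.0,
                        seed: int = 0) -> np.ndarray:
    """Probe the first feasible radius and build a linear grid from it.

    Feasibility is probed with short single-seed pre-runs on a coarse
    0.25-Angstrom ladder: a radius is feasible once the best individual
    escapes the wall penalty.  The grid spans ``[0.95 * a_f, 0.95 * a_f
    + span]`` with ``n_radii`` points.
    """
    forcefield = forcefield or default_forcefield()
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    # lower bound: half the largest body-frame extent cannot possibly fit tighter
    r_min = max(0.3, min(np.abs(m.coords_body).max() for m in molecules) * 0.3)
    probe = SearchSettings(population=40, offspring=40, generations=60, seeds=(seed,))
    a = r_min
    while a < 25.0:
        kw = {} if eta is None else {"eta": eta}
        res = optimize(molecules, copies=copies, tube=TubeModel(a, **kw),
                       settings=probe, forcefield=forcefield)
        if res.feasible:
            break
        a += 0.25
    else:
        raise RuntimeError("no feasible radius found below 25 A")
    start = 0.95 * a
    return np.linspace(start, start + span, n_radii)


def analyze_curve(radii, emin):
    """Spline a sampled E_min(a) curve and extract a0 and its interior minima.

    Returns ``(spline, a0, minima, diagnostics)`` where ``minima`` is a
    list of ``(a, E_spline)`` stationary minima sorted by energy and
    ``a0`` is the smallest downward zero crossing (None if the grid does
    not bracket one).
    """
    radii = np.asarray(radii, dtype=float)
    emin = np.asarray(emin, dtype=float)
    spline = CubicSpline(radii, emin)  # not-a-knot ends
    diagnostics: list[str] = []

    a0 = None
    for k in range(len(radii) - 1):
        if emin[k] > 0.0 >= emin[k + 1]:
            a0 = float(brentq(spline, radii[k], radii[k + 1]))
            break
    if a0 is None:
        diagnostics.append("no sign change on the grid: a0 not bracketed")

    # interior stationary minima: real roots of dE/da with positive curvature
    deriv = spline.derivative()
    second = deriv.derivative()
    roots = deriv.roots(extrapolate=False)
    roots = np.real(roots[np.isreal(roots)])
    minima: list[tuple[float, float]] = []
    for r in sorted(roots):
        if not (radii[0] < r < radii[-1]) or second(r) <= 0:
            continue
        if minima and abs(r - minima[-1][0]) < 1e-6:
            continue
        minima.append((float(r), float(spline(r))))
    if not minima:
        diagnostics.append("no interior minimum on the grid")
    minima.sort(key=lambda t: t[1])
    return spline, a0, minima, diagnostics


def scan(molecules, copies: int = 1, radius_grid=None,
         settings: SearchSettings | None = None,
         forcefield: ForceField | None = None,
         eta: float | None = None) -> LandscapeResult:
    """Sweep tube radii, spline E_min(a), locate a0 and the optimal radii."""
    forcefield = forcefield or default_forcefield()
    settings = settings or SearchSettings()
    if radius_grid is None:
        radius_grid = default_radius_grid(molecules, copies, eta=eta, forcefield=forcefield)
    radius_grid = np.asarray(radius_grid, dtype=float)
    if len(radius_grid) < 6:
        raise ValueError("radius grid needs at least 6 points")
    if np.any(np.diff(radius_grid) <= 0):
        raise ValueError("radius grid must be strictly increasing")

    kw = {} if eta is None else {"eta": eta}
    per_radius, emin = [], []
    for a in radius_grid:
        res = optimize(molecules, copies=copies, tube=TubeModel(float(a), **kw),
                       settings=settings, forcefield=forcefield)
        per_radius.append(res)
        emin.append(res.best_energy)
    emin = np.asarray(emin)

    diagnostics: list[str] = []
    feasible = emin < PENALTY_SCALE
    if not np.all(feasible):
        diagnostics.append(
            f"{int((~feasible).sum())} grid radii infeasible (wall-penalized); "
            "spline restricted to the feasible range"
        )
    radii_f = radius_grid[feasible]
    emin_f = emin[feasible]
    if len(radii_f) < 6:
        raise RuntimeError("fewer than 6 feasible grid radii; widen the grid")
    spline, a0, stationary, notes = analyze_curve(radii_f, emin_f)
    diagnostics.extend(notes)

    minima: list[Minimum] = []
    for r, e_spline in stationary:
        reopt = optimize(molecules, copies=copies, tube=TubeModel(float(r), **kw),
                         settings=settings, forcefield=forcefield)
        minima.append(Minimum(a=float(r), energy_spline=float(e_spline),
                              energy=reopt.best_energy, result=reopt))
    minima.sort(key=lambda m: m.energy)

    return LandscapeResult(
        radii=radius_grid, emin=emin, spline=spline, a0=a0,
        minima=minima, per_radius=per_radius, diagnostics=diagnostics,
    )
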