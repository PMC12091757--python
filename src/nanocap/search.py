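"""Evolutionary minimization of the encapsulation energy.

The search follows the single-objective degenerate form of U-NSGA-III:
with one objective, non-dominated sorting reduces to sorting by energy
and niching reduces to elitist tournament selection, so the loop is a
(mu + lambda) generational GA — binary tournament parent selection,
simulated-binary crossover (SBX), polynomial mutation, merge parents
with offspring, and truncate to the best mu by energy.  Every run is
fully reproducible from its seed; multi-seed batteries guard against
entrapment in local minima, and their distinct outcomes can be grouped
with :func:`categorize_minima`.

Decision variables are the 5 rigid-body degrees of freedom per molecule:
x, y, z in [-16, 16] Angstrom and theta_x, theta_y in [-pi, pi].  The
initial population draws (x, y) inside the tube cross-section rather
than the full box — the box is mostly wall-penalized when the tube is
narrow — while crossover and mutation may still explore the whole box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .continuum import TubeModel
from .forcefield import ForceField, default_forcefield
from .molecule import Molecule, POSITION_BOUND
from .system import Configuration, PopulationEvaluator, PENALTY_SCALE, WALL_MARGIN, total_energy

__all__ = ["SearchSettings", "SearchResult", "optimize", "categorize_minima"]


@dataclass
class SearchSettings:
    """Hyperparameters of the evolutionary search.

    Defaults are sized for 5-30 decision variables: population and
    offspring 200, up to 400 generations with early stopping once the
    best energy improves by less than ``stall_tol`` over
    ``stall_window`` generations, SBX (index 15, rate 0.9), polynomial
    mutation (index 20, rate 1/n_var), 8 seeds.
    """

    population: int = 200
    offspring: int = 200
    generations: int = 400
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    crossover_eta: float = 15.0
    crossover_prob: float = 0.9
    mutation_eta: float = 20.0
    mutation_prob: float | None = None  # default 1 / n_var
    stall_window: int = 50
    stall_tol: float = 1e-4
    #: initial niche radius for diversity-preserving survival, as a fraction
    #: of each variable's span (Chebyshev metric); annealed linearly to zero
    #: over the run so late generations refine freely; 0 disables clearing
    niche_eps: float = 0.1
    #: iterations of the (1+1)-ES refinement of the per-seed best individual
    #: after the generational loop (self-adaptive step size, derivative-free);
    #: 0 disables polishing
    polish_iters: int = 400

    def __post_init__(self):
        if self.population < 10:
            raise ValueError("population must be >= 10")
        if len(self.seeds) < 1:
            raise ValueError("at least one seed required")


@dataclass
class SearchResult:
    """Best configuration found across all seeds, with per-seed histories."""

    best_energy: float
    best_configuration: Configuration
    best_seed: int
    trajectories: dict[int, np.ndarray]  # seed -> best energy per generation
    per_seed_best: dict[int, float] = field(default_factory=dict)
    category: str | None = None

    @property
    def feasible(self) -> bool:
        """False when even the best individual carries the wall penalty."""
        return self.best_energy < PENALTY_SCALE


def _bounds(n_mol: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.tile([-POSITION_BOUND] * 3 + [-math.pi] * 2, n_mol)
    hi = np.tile([POSITION_BOUND] * 3 + [math.pi] * 2, n_mol)
    return lo, hi


def _initial_population(rng, n_mol, pop, tube) -> np.ndarray:
    X = np.empty((pop, 5 * n_mol))
    r_max = max(tube.a - WALL_MARGIN, 1e-3)
    for m in range(n_mol):
        r = r_max * np.sqrt(rng.random(pop))
        phi = rng.uniform(-math.pi, math.pi, pop)
        X[:, 5 * m + 0] = r * np.cos(phi)
        X[:, 5 * m + 1] = r * np.sin(phi)
        X[:, 5 * m + 2] = rng.uniform(-POSITION_BOUND, POSITION_BOUND, pop)
        X[:, 5 * m + 3] = rng.uniform(-math.pi, math.pi, pop)
        X[:, 5 * m + 4] = rng.uniform(-math.pi, math.pi, pop)
    return X


def _sbx(rng, parents, lo, hi, eta, prob):
    """Simulated binary crossover on consecutive parent pairs."""
    child = parents.copy()
    n_pairs = len(parents) // 2
    for k in range(n_pairs):
        p1, p2 = child[2 * k], child[2 * k + 1]
        if rng.random() > prob:
            continue
        swap = rng.random(p1.shape) < 0.5
        u = rng.random(p1.shape)
        beta = np.where(
            u <= 0.5,
            (2 * u) ** (1.0 / (eta + 1)),
            (1.0 / (2 * (1 - u))) ** (1.0 / (eta + 1)),
        )
        mean = 0.5 * (p1 + p2)
        diff = 0.5 * np.abs(p1 - p2)
        c1 = mean - beta * diff
        c2 = mean + beta * diff
        c1b = np.where(swap, c2, c1)
        c2b = np.where(swap, c1, c2)
        child[2 * k] = np.clip(c1b, lo, hi)
        child[2 * k + 1] = np.clip(c2b, lo, hi)
    return child


def _polynomial_mutation(rng, X, lo, hi, eta, prob):
    span = hi - lo
    mask = rng.random(X.shape) < prob
    u = rng.random(X.shape)
    delta = np.where(
        u < 0.5,
        (2 * u) ** (1.0 / (eta + 1)) - 1.0,
        1.0 - (2 * (1 - u)) ** (1.0 / (eta + 1)),
    )
    return np.clip(np.where(mask, X + delta * span, X), lo, hi)


def _select_with_diversity(Xall, Fall, order, mu, span, eps):
    """Energy-ordered survival with niche clearing.

    Keeps candidates in ascending-energy order, skipping any whose
    normalized Chebyshev distance to an already-kept survivor is below
    ``eps`` (the niche leader is always the best of its niche); if
    clearing leaves fewer than ``mu`` survivors, the best skipped
    candidates fill the remainder.
    """
    if eps <= 0:
        keep = order[:mu]
        return Xall[keep], Fall[keep]
    kept: list[int] = []
    skipped: list[int] = []
    Xn = Xall / span  # normalized coordinates
    for idx in order:
        if len(kept) == mu:
            break
        if kept:
            dmin = np.abs(Xn[kept] - Xn[idx]).max(axis=1).min()
            if dmin < eps:
                skipped.append(idx)
                continue
        kept.append(idx)
    if len(kept) < mu:
        kept.extend(skipped[: mu - len(kept)])
    keep = np.array(kept)
    return Xall[keep], Fall[keep]


def _run_single_seed(evaluator, tube, settings, seed):
    rng = np.random.default_rng(seed)
    n_mol = evaluator.n_mol
    n_var = evaluator.n_var
    lo, hi = _bounds(n_mol)
    mut_prob = settings.mutation_prob if settings.mutation_prob is not None else 1.0 / n_var

    X = _initial_population(rng, n_mol, settings.population, tube)
    F = evaluator.evaluate(X)
    history = [float(F.min())]

    for gen in range(settings.generations):
        # binary tournament by energy
        idx = rng.integers(0, settings.population, size=(settings.offspring, 2))
        winners = np.where(F[idx[:, 0]] <= F[idx[:, 1]], idx[:, 0], idx[:, 1])
        parents = X[winners]
        children = _sbx(rng, parents, lo, hi, settings.crossover_eta, settings.crossover_prob)
        children = _polynomial_mutation(rng, children, lo, hi, settings.mutation_eta, mut_prob)
        Fc = evaluator.evaluate(children)
        # elitist (mu + lambda) truncation with diversity preservation:
        # walk the merged pool in energy order, keep the best of each
        # niche (clearing), fill up with best remaining if short
        Xall = np.vstack([X, children])
        Fall = np.concatenate([F, Fc])
        order = np.argsort(Fall, kind="stable")
        eps = settings.niche_eps * max(0.0, 1.0 - gen / (0.7 * settings.generations))
        X, F = _select_with_diversity(
            Xall, Fall, order, settings.population, hi - lo, eps
        )
        history.append(float(F[0]))
        w = settings.stall_window
        if len(history) > w and history[-1 - w] - history[-1] < settings.stall_tol:
            break
    best = int(np.argmin(F))
    x_best, f_best = X[best].copy(), float(F[best])
    if settings.polish_iters > 0 and f_best < PENALTY_SCALE:
        x_best, f_best = _polish_es(evaluator, x_best, f_best, rng, lo, hi,
                                    settings.polish_iters)
        history.append(f_best)
    return x_best, f_best, np.array(history)


def _polish_es(evaluator, x, f, rng, lo, hi, iters, batch=16):
    """(1+1)-evolution-strategy refinement with 1/5th-rule step adaptation.

    Purely mutation-driven local descent on the penalized objective:
    each step proposes a small batch of Gaussian perturbations, accepts
    the best if it improves, and grows/shrinks the step size on
    success/failure.  Keeps the search evolutionary end to end while
    recovering the last fraction of a kcal/mol the generational loop
    leaves on the table.
    """
    span = hi - lo
    sigma = 0.01
    for _ in range(iters):
        cand = np.clip(x + sigma * span * rng.standard_normal((batch, x.size)), lo, hi)
        fc = evaluator.evaluate(cand)
        k = int(np.argmin(fc))
        if fc[k] < f:
            x, f = cand[k].copy(), float(fc[k])
            sigma = min(sigma * 1.2, 0.1)
        else:
            sigma = max(sigma * 0.93, 1e-7)
    return x, f


def optimize(molecules, copies: int = 1, tube: TubeModel | None = None,
             settings: SearchSettings | None = None,
             forcefield: ForceField | None = None) -> SearchResult:
    """Minimize the total energy of ``copies`` of each molecule in ``tube``.

    ``molecules`` may be a single :class:`Molecule` or a sequence; each
    is replicated ``copies`` times.  Runs once per seed in
    ``settings.seeds`` and returns the best result over all seeds with
    the per-seed best-energy trajectories attached.  If the tube cannot
    host the molecules at all, every individual stays wall-penalized and
    the result reports ``feasible = False``.
    """
    if tube is None:
        raise ValueError("a TubeModel is required")
    settings = settings or SearchSettings()
    forcefield = forcefield or default_forcefield()
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    expanded = [m for m in molecules for _ in range(copies)]
    evaluator = PopulationEvaluator(expanded, tube, forcefield)

    trajectories: dict[int, np.ndarray] = {}
    per_seed_best: dict[int, float] = {}
    best_vec, best_e, best_seed = None, np.inf, None
    for seed in settings.seeds:
        vec, e, hist = _run_single_seed(evaluator, tube, settings, seed)
        trajectories[seed] = hist
        per_seed_best[seed] = e
        if e < best_e:
            best_vec, best_e, best_seed = vec, e, seed

    config = Configuration.from_vector(best_vec, expanded, tube)
    if best_e < PENALTY_SCALE:
        # re-evaluate exactly; evaluator is exact on feasible vectors
        best_e = total_energy(config, forcefield).total
    return SearchResult(
        best_energy=float(best_e),
        best_configuration=config,
        best_seed=best_seed,
        trajectories=trajectories,
        per_seed_best=per_seed_best,
    )


def categorize_minima(results, energy_tol: float = 1.0, d_tol: float = 0.2,
                      omega_tol: float = 10.0):
    """Group search results into distinct minima.

    Two results belong to the same group when their best energies agree
    within ``energy_tol`` (kcal/mol) and their geometric descriptors
    agree: every wall distance d within ``d_tol`` (Angstrom) and every
    consecutive separation angle within ``omega_tol`` (degrees).  The
    lowest-energy group is labeled ``"global"``, the others ``"local"``;
    labels are written back onto the results.

    Returns the list of groups (each a list of results), global first.
    """
    from .descriptors import describe

    if len(results) < 2:
        raise ValueError("categorize_minima needs at least two results")

    feats = []
    for r in results:
        table = describe(r.best_configuration)
        feats.append((r.best_energy, np.array(table.d), np.array(table.omega)))

    groups: list[list[int]] = []
    for i, (e, d, om) in enumerate(feats):
        placed = False
        for g in groups:
            e0, d0, om0 = feats[g[0]]
            if (
                abs(e - e0) <= energy_tol
                and d.shape == d0.shape
                and np.all(np.abs(d - d0) <= d_tol)
                and (om.size == 0 or np.all(np.abs(om - om0) <= omega_tol))
            ):
                g.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])
    groups.sort(key=lambda g: min(feats[i][0] for i in g))
    out = []
    for rank, g in enumerate(groups):
        label = "global" if rank == 0 else "local"
        members = [results[i] for i in g]
        for r in members:
            r.category = label
        out.append(members)
    return out
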