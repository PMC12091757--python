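# Methods

## Model

The package computes the van der Waals energy of rigid drug molecules
inside an idealized single-walled carbon nanotube.  The tube is an
infinite straight cylinder aligned with the z-axis, characterized only
by its radius *a* (Å) and a uniform atomic surface density η, defaulting
to the graphene-sheet value 0.3812 atoms/Å².  Chirality, finite length,
tube flexibility, electrostatics and solvent are all outside the model:
the only interaction is the 6–12 Lennard-Jones potential, and the tube
wall is featureless.  These assumptions make the atom–wall energy a
closed-form function of the atom's axial distance δ, so evaluating a
configuration costs a handful of special-function calls rather than a
sum over thousands of wall atoms — the point of the hybrid
discrete–continuum formulation.

Per-element Lennard-Jones parameters are the UFF nonbonded values
(well depth ε in kcal/mol; vdW minimum distance used directly as σ in
Å), shipped as a plain-text table (`nanocap/data/uff_nonbonded.txt`)
together with IUPAC standard atomic weights; users can substitute their
own table via `--forcefield`.  Pairs mix by geometric mean (ε) and
arithmetic mean (σ).  Units are Å and kcal/mol throughout.

## Numerical evaluation of the wall integral

The closed form for Iₙ contains ₂F₁(n−½, ½; 1; w) with
w = −4aδ/(a−δ)², which diverges as the atom approaches the wall and
makes naive evaluation unstable.  We evaluate through the Pfaff
transformation, ₂F₁(m, ½; 1; w) = (1−w)^(−m) ₂F₁(m, ½; 1; w/(w−1)),
whose argument 4aδ/(a+δ)² stays in [0, 1); the transformed expression
simplifies to 2πa·B(n−½,½)·₂F₁(n−½,½;1;4aδ/(a+δ)²)/(a+δ)^(2n−1).
Agreement with adaptive 2-D quadrature is at the 1e-10 relative level
across δ/a ∈ [0, 0.999] (tested).  Atoms on or outside the wall
(δ ≥ a) are a domain error: only encapsulation is modeled.

## Total energy and constraint handling

For n molecules the energy is the sum of per-atom wall terms (each
atom's element mixed with the wall carbon) plus exact atom–atom
Lennard-Jones double sums between molecules — no cutoffs, neighbor
lists or periodicity, since systems stay below a few hundred atoms.
During optimization, any configuration placing an atom within 0.05 Å
of the wall (or beyond) receives a finite penalty 10⁶·(1 + worst
violation in Å) instead of an exception, keeping the evolutionary
fitness defined on the whole box; reported energies are always exact
re-evaluations of feasible configurations, and the vectorized
population evaluator agrees with the scalar path to 1e-9 (tested).

## Evolutionary search

Each molecule contributes five decision variables: x, y, z ∈ [−16, 16]
Å and θx, θy ∈ [−π, π] (intrinsic x-then-y rotations about the center
of mass, applied before translation; the composition order is a
package convention).  With a single objective, reference-direction
niching degenerates, so the search is an elitist (μ+λ) genetic
algorithm: binary tournament by energy, simulated-binary crossover
(index 15, rate 0.9), polynomial mutation (index 20, rate 1/5n), merge
and truncate.  Two refinements matter in practice:

- **Diversity-preserving survival.**  Plain truncation collapses the
  population before cooperative multi-molecule arrangements (stacked
  pairs, trellis patterns) are found.  Survival therefore walks the
  merged pool in energy order and skips candidates within a niche
  radius (Chebyshev distance, 10% of each variable's span) of an
  already-kept survivor; the radius anneals linearly to zero over the
  first 70% of the run so late generations exploit freely.
- **(1+1)-ES polish.**  After the generational loop, the best
  individual is refined by a derivative-free (1+1) evolution strategy
  (Gaussian steps, 1/5th-rule step adaptation, 400 iterations by
  default).  This recovers the last fraction of a kcal/mol and
  sharpens geometric descriptors without introducing gradient-based
  machinery.

The initial population draws (x, y) uniformly over the tube
cross-section rather than the full box (the box is almost entirely
wall-penalized for narrow tubes); crossover and mutation still explore
the full bounds.  Defaults are population = offspring = 200, up to 400
generations with early stop when the best energy improves by less than
1e-4 kcal/mol over 50 generations, and 8 seeds; every run is bit-
reproducible from its seed list.  Distinct minima across seeds are
grouped by energy (1 kcal/mol), wall distance (0.2 Å) and separation
angle (10°), the lowest group labeled global.

## Radius landscape

The minimized energy E_min(a) is sampled on 10–15 radii, interpolated
with a not-a-knot cubic spline, and two landmarks extracted: a₀, the
smallest downward zero crossing (bracketed on the grid, polished by
Brent root finding), and the interior spline minima (derivative roots
with positive curvature), at each of which the system is re-optimized
to produce the final configuration.  The default grid spans
[0.95·a_f, 0.95·a_f + 4 Å] in 12 steps, where a_f is the first radius
a short pre-run finds feasible; reproduction workflows pass explicit
grids.

## Descriptors

For each optimized configuration: d = a − √(x²+y²) (center of mass to
wall), γ = acute angle between the molecular plane normal (smallest
principal axis of the mass-weighted coordinate covariance, sign-
canonicalized) and the radial direction, and for consecutive molecules
after sorting by center-of-mass z (ties by azimuth): ω = angle between
the two cross-section projections and ξ = |z_i − z_j|.  γ is folded
into [0°, 90°] because the normal's sign is arbitrary; ω of a molecule
whose projection sits within 1e-6 Å of the axis is flagged
ill-conditioned (near-axis molecules make the angle numerically
meaningless).  The pair-reporting order is a package convention; an
equivalent configuration can therefore pair molecules differently than
an external reference does.

## Molecules

Study drugs are built at run time from SMILES: an ETKDG conformer
ensemble (8 + 5 per rotatable bond, capped at 48, fixed seed per drug),
each relaxed with MMFF94s with the Coulomb term disabled, keeping the
lowest-energy conformer.  Disabling vacuum electrostatics mirrors how
public compound databases generate their single 3D records and avoids
folding flexible molecules into unrepresentative H-bonded balls.
Methylene blue is modeled as the chloride salt (the counterion rides
along as part of the rigid body).  Conformers are deterministic for a
fixed RDKit version but they are synthetic: for rigid, planar drugs
(fluorouracil, proflavine, methylene blue) they track the reference
database geometries closely, while for doxorubicin — the only flexible
drug, with a glycosidic linkage and several rotatable bonds — the
synthetic conformer is measurably bulkier than the reference record,
which systematically weakens its computed wall binding (see
Limitations).  Geometric fixtures (single atom, dimer, hexagon ring,
tetrahedron) provide exact, download-free test systems.

## Problem sizes used in tests and the acceptance script

Reproduction runs use search batteries sized for a desk machine:
population 100–150, 300–500 generations with early stopping, 2–6 seeds
(more seeds for two-molecule systems, whose cooperative minima have a
per-seed discovery rate well below 1).  These are smaller than the
package defaults; energies from the battery sizes agree with
fully-converged runs to a few tenths of a kcal/mol for one- and
two-molecule systems.  Three-molecule systems at these sizes stop a
few percent above the best known packing energies, which leaves wall
distances and tilt angles accurate but slightly noisier.

## What the synthetic tests do and do not show

The oracle tests (quadrature equivalence, golden-section recovery,
dense-grid landscape recovery, symmetry invariances) validate the
mathematics and the optimizer on systems with independently computable
truth.  The drug-reproduction tests validate the full pipeline against
published values, but through synthetic conformers: agreement there
supports the model and workflow, not the fidelity of any particular
conformer to the original database record.

## Known limitations

- Doxorubicin's synthetic conformer binds ~25–30% weaker than the
  published values at the published optimal radius, and its multi-copy
  arrangements can differ qualitatively; all doxorubicin energy
  comparisons inherit this conformer sensitivity.
- Two-molecule minimum energies for strongly stacking drugs
  (methylene blue) can come out 2–4% deeper than published values —
  the same conformer drift in the opposite direction.
- The separation angle ω of near-axis molecules is intrinsically
  ill-conditioned: nearly degenerate minima (energy differences of
  ~0.1 kcal/mol) can have very different ω, so reproducing published ω
  values for tightly-fitting tubes is sensitive to search
  stochasticity.
- The infinite-tube assumption shifts absolute energies of long tubes
  but not equilibrium geometry; no finite-length or multi-wall
  corrections are provided.
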