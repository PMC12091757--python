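# nanocap

Energetics of small-molecule drugs encapsulated in carbon nanotubes,
computed with a hybrid discrete–continuum Lennard-Jones model and an
evolutionary configuration search.

## Who this is for

Researchers studying non-covalent drug loading of single-walled carbon
nanotubes (CNTs) — e.g. screening which tube radii can host a drug, how
strongly it binds, and how multiple copies arrange themselves — without
running full molecular-dynamics simulations.

## The model

A drug molecule is a rigid body of discrete atoms; the nanotube is an
infinite smooth cylinder of radius *a* with a uniform atomic surface
density η = 0.3812 atoms/Å² (the graphene value).  Two non-bonded atoms
interact through the 6–12 Lennard-Jones potential

    Φ(ρ) = −A/ρ⁶ + B/ρ¹²,   A = 2εσ⁶,  B = εσ¹²,

with UFF well depths ε and van der Waals diameters σ, mixed across
species by ε_ij = √(ε_i ε_j), σ_ij = (σ_i + σ_j)/2.  Averaging the wall
atoms over the cylinder surface turns the atom–wall energy into surface
integrals Iₙ = ∫ ρ⁻²ⁿ dS with the closed form

    Iₙ = 2πa/(a−δ)^(2n−1) · B(n−½, ½) · ₂F₁(n−½, ½; 1; −4aδ/(a−δ)²),

where δ is the atom's distance from the tube axis, B the beta function
and ₂F₁ the Gauss hypergeometric function, giving

    E_p(δ) = η (−A·I₃ + B·I₆).

The total energy of *n* molecules is the sum of these continuum wall
terms over all atoms plus discrete atom–atom Lennard-Jones sums between
molecules.  Each molecule carries five degrees of freedom (x, y, z,
θx, θy); the 5n-dimensional energy is minimized by a single-objective
elitist genetic algorithm (SBX crossover, polynomial mutation,
diversity-preserving survival, multi-seed batteries).  Scanning the
minimized energy over tube radii and spline-interpolating yields the
zero-energy radius a₀ (the smallest tube that can host the load) and
the optimal radius.  Equilibrium configurations are summarized by four
descriptors: wall distance d, separation angle ω, tilt angle γ and
axial offset ξ.

## Worked example

Optimize one fluorouracil molecule in a tube of radius 10 Å:

```sh
nanocap optimize --molecule FU --radius 10 --seeds 1,2 \
    --pop-size 100 --generations 300 --out fu_a10
```

which prints (energies in kcal/mol, lengths in Å):

```
E_min = -19.6783 kcal/mol (seed 2)
molecule 1: d = 3.4710 A, gamma = 1.80 deg
```

The molecule binds with about −19.7 kcal/mol, sits 3.47 Å from the
wall — essentially the graphite interlayer spacing, as expected for a
flat aromatic ring — and its ring plane is parallel to the wall (tilt
below 2°).  Sweep tube radii to find where encapsulation becomes
favorable and where it is optimal:

```sh
nanocap scan --molecule FU --radius-grid 4.4 7.0 14 --seeds 1,2 \
    --pop-size 100 --generations 300 --out fu_scan
```

```
a0 = 4.5217
global: a = 5.0602, Emin = -27.2138 kcal/mol
```

i.e. a tube must have radius ≥ 4.52 Å to host fluorouracil at all, and
a 5.06 Å tube binds it most strongly.  Each run directory contains the
optimized structure (`optimized.xyz`), energy breakdown, descriptor
table, per-seed trajectories and a log with seeds and the force-field
checksum, so results can be re-derived bit-identically.

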