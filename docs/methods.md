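# Methods

## The docking model

minidock implements the classic rigid-component / flexibase docking scheme.
The receptor is reduced to (a) a set of *matching spheres* — labelled 3-D
points marking positions in the binding site where ligand heavy atoms are
likely to sit — and (b) four precomputed scalar energy grids (van der Waals
repulsive and attractive, electrostatic potential, fractional desolvation).
The ligand is a *hierarchy*: one topology (atoms, bonds, partial charges,
per-atom desolvation terms) with an ensemble of pre-built conformers that all
share the coordinates of a *rigid component*, typically the largest fused
ring system.  Only whole input conformations are docked; conformers are never
recombined from fragments of different inputs, which historically produced
internally clashing geometries that acted as high-scoring artifacts.

### Orientation sampling

Ligand orientations are generated by *clique matching*: choosing
`node_count` (= 4) rigid-component heavy atoms and 4 receptor spheres such
that all C(4,2) = 6 internal distances agree pairwise within a distance
tolerance — the matched points form congruent tetrahedra up to the
tolerance.  Enumeration is complete over all ligand 4-subsets and injective
receptor assignments (no histogram pre-binning, no minimum-separation
filter), and is emitted in a fixed canonical order (lexicographic by sorted
ligand indices, then receptor indices).  Two consequences, both covered by
tests:

* **monotonicity** — every correspondence found at tolerance t is found at
  any t' >= t, so raising the tolerance strictly grows the orientation set;
* **determinism** — the same inputs always give the byte-identical output;
  there is no randomness anywhere in the sampler or the engine.

An adaptive driver walks the tolerance along a schedule (default minimum
0.05 A, increment 0.05 A, maximum 1.5 A) until the number of matches reaches
the *match goal* — the single knob controlling how much orientation sampling
a run does.  All matches at the final tolerance are kept, never truncated to
the goal: truncation would break the guarantee that a larger goal yields a
superset of a smaller one (and hence that the best docked energy is
non-increasing in the match goal).

Each correspondence is turned into a rigid transform by least-squares
superposition (Kabsch via SVD) of the matched ligand spheres onto the
receptor spheres.  Reflections are forced out (determinant +1): docking the
mirror image of a molecule is not physically meaningful.  Near-collinear
sphere subsets (singular-value ratio of the centered ligand points below
1e-6) define no orientation and are discarded at this step — deliberately
*after* enumeration, so the complete-matching contract is untouched.

### Scoring

A pose's energy is a sum of per-atom terms read off the grids by trilinear
interpolation at the atom position x:

    E_atom = sqrt(a) R(x) - sqrt(b) A(x) + q Phi(x) + dE_solv D(x)

where R and A are the receptor's sqrt(A)/r^12 and sqrt(B)/r^6 sums (the
geometric-combination convention, which is what lets a single pair of grids
serve every atom type), Phi the electrostatic potential in kcal/(mol.e) and
D the dimensionless fractional desolvation.  Interpolation has a reference
path (8-corner blend) and a precomputed path that stores every interpolation
cube's 8 corner values contiguously; the two must agree to 1e-10 relative
(tested on 10^4 random queries), and the fast table costs ~8x the grid
memory.  Atoms outside the lattice reject the pose — grids are trimmed to
the meaningful region and nothing is extrapolated.

The *bump filter* replaces an older distance-cutoff bump grid: the running
sum of the (non-negative) repulsive vdW contributions, accumulated in atom
order, is compared to a limit (default 50 kcal/mol); exceeding it abandons
the pose immediately.  A pose that only scores well by burying an atom in
the repulsive core is not a physically realistic pose, however favorable its
electrostatics.  We test the cumulative sum, not each atom separately;
whichever convention is used, the survivor sets at limits 10 <= 20 <= 50 <=
unlimited are nested, and that nesting (not the convention) is the tested
contract.

The best N poses per molecule are kept by bounded insertion sort on total
energy, ties broken by (orientation index, conformer index).  Per-atom,
per-term breakdowns are carried on every pose and can be written to the mol2
output.  The ligand's internal (builder) conformer energy is carried through
to output but *not* added to the docking score.

### Conformer hygiene

Two build-time operations act on the ensemble:

* **hydroxyl rotamer reset** — small-molecule crystal survey data show
  aromatic hydroxyl protons overwhelmingly in the ring plane, while 3-D
  builders often leave them out of plane.  For each O-H on an sp2 carbon
  (aromatic or double-bonded), the two in-plane rotamers (heavy-ref-C-O-H
  dihedral 0 and pi) are generated; on an sp3 carbon, three staggered
  rotamers at 2pi/3 spacing.  The product over independent hydroxyls is
  capped at 32 combinations, pruning later-indexed hydroxyls to their first
  rotamer first.  sp2 perception is deliberately simple (aromatic ring bond
  or any double bond on the attached carbon).
* **energy-window filter** — only conformers within a window (e.g. 12.5, 15
  or 30 kcal/mol) of the ensemble minimum are retained; the minimum is always
  kept and order is preserved.  Wider windows keep supersets.

### Rigid-component perception

The rigid component is the largest fused ring system: ring bonds are the
non-bridge edges of the heavy-atom graph, so ring systems joined by a
rotatable single bond (biphenyl) are *not* merged.  Acyclic molecules fall
back to the largest heavy-atom set connected solely by non-rotatable bonds
(terminal, amide, double/triple/aromatic).  Fewer than 3 rigid heavy atoms
flags the molecule undockable (matching itself needs 4).  Ties break to the
lowest atom indices.

## Evaluation metrics

* **ROC / AUC** — scores ranked ascending (best first); tied blocks collapse
  to single segments, making the trapezoidal area the average over tie
  orderings.
* **Adjusted logAUC** — the ROC area with a log10 false-positive axis over
  [lambda, 1], lambda = 0.001, normalised by log10(1/lambda) and expressed
  in percent, minus the random-classifier reference 100(1-lambda)/ln(1/lambda)
  (= 14.462% at lambda 0.001).  Zero therefore means random enrichment; a
  perfect classifier reaches ~85.54.  Each piecewise-linear curve segment is
  integrated against d(log10 FPR) in closed form rather than by a vertex
  trapezoid: the two coincide on the axis-parallel segments of a staircase
  ROC, but only the closed form is exact on the tie-block diagonal, which is
  what makes "adjusted logAUC of an all-tied screen = 0" hold to machine
  precision.
* **EF1** — fraction of ligands in the top ceil(0.01 N) of the ranked list,
  divided by 0.01; ties break by input order (stable sort).  Screens with
  0.01 N < 1 are rejected rather than silently rounded.
* **Hungarian RMSD** — heavy-atom RMSD under the optimal same-element
  assignment (Kuhn-Munkres on squared distances), so symmetry-equivalent
  atoms cannot inflate the deviation.
* **Critical-contact RMSD** — the same optimal assignment, but of a small
  reference atom set (2-5 pharmacophore-defining atoms) against *any* pose
  atoms of matching element.  The assignment is globally optimal per
  element, not greedy.  A pose lacking a required element has *undefined*
  RMSD — it is excluded, and library aggregation uses the median over
  defined values.

## Synthetic fixtures — what they emulate and what they do not

All inputs are generated, seeded and self-verifying:

* the **toy matching system** (3 ligand spheres, 4 receptor spheres) is an
  exact 3-4-5 triangle against a perturbed 3x4 rectangle, built so 3-node
  matching finds exactly 2 correspondences at 0.1 A and 4 at 0.2 A, and none
  at 0 (generic position).  The counts, verified by brute force at build
  time, are the contract; the coordinates are this package's own.
* the **analytic field** is a handful of pseudo-receptor atoms with 12-6
  Lennard-Jones + Coulomb (relative dielectric 4, clamped inside a 0.8 A
  core) + Gaussian desolvation potentials, sampled onto grids.  It stands in
  for force-field and Poisson-Boltzmann receptor grids: same shape and
  units, none of the physics of a real protein environment.
* the **planted site** places attractive wells (with mild repulsive cores
  and opposite charges) at a known ligand pose's heavy atoms and receptor
  spheres at its rigid atoms — mirroring preparation pipelines that seed
  spheres from crystallographic ligand coordinates — and verifies at build
  time that the planted pose scores below -1 kcal/mol and survives the
  default bump limit.  Grids use 0.4 A spacing, a 4 A margin, and stay
  within 64^3 points.
* **hierarchies** are irregular planar aromatic rings (the irregularity
  breaks ring symmetry, so self-matches need raised tolerances) with
  rotatable tails generating the conformers and optional out-of-plane
  hydroxyls; charges are seeded with total charge exactly zero.  The
  builder settings they emulate (0.4 A RMSD cutoff, up to 2000 conformers)
  are recorded as metadata only.
* **score sets** draw ligand scores from N(-separation, 1) and decoys from
  N(0, 1).

Passing tests on these fixtures demonstrates the algorithmic contracts —
completeness, monotonicity, determinism, nesting, metric identities — on
inputs whose ground truth is known by construction.  They do not demonstrate
enrichment on real targets: the fixtures have no protein sterics,
desolvation physics, or decoy property matching.

## Numerical choices

* Tolerance-schedule arithmetic uses minimum + k*increment with a 1e-12
  slack at the maximum, so float accumulation cannot skip the last step.
* Degenerate-geometry threshold: singular-value ratio < 1e-6.
* Rigid-component consistency across conformers: 1e-3 A (direct or after
  superposition).
* Hydroxyl dihedrals are set by rotating the proton about the C-O axis and
  verified to 1e-9 rad.
* Score tables are written with fixed %.6f formatting so identical runs are
  byte-identical files.
* The no-pose sentinel in score tables is +1000 kcal/mol with an explicit
  status column, avoiding NaN-ordering ambiguity downstream.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
200 random matcher-oracle systems of <= 8 spheres per side, 20-molecule
libraries, grids of at most 64^3 points at 0.4 A spacing, 10 planted-site
recoveries, 50-seed null-enrichment simulations.  The full suite completes
in well under a minute on one core.

## Known limitations

* Single rigid receptor; no minimization, receptor flexibility or covalent
  docking.  Users parallelize across molecules externally.
* The vdW parameter table is generic (element-typed Lennard-Jones
  magnitudes), adequate for grid scoring mechanics, not a fitted force
  field.
* Conformer generation, charge/desolvation derivation and receptor grid
  generation from structures are out of scope; fixtures or imported files
  supply them.
* Orientations are not deduplicated; near-duplicate correspondences are
  scored and sorted out by energy, so orientation counts are raw counts.
* Each (orientation, conformer) pair is scored independently; a clash in one
  conformer does not skip the remaining conformers of that orientation.
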