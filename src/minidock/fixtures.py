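"""Deterministic synthetic fixtures for every input class.

Real docking inputs come from a long preparation pipeline (receptor grids
from force-field and Poisson-Boltzmann calculations, ligand conformers from a
commercial builder).  This module generates physically-shaped stand-ins for
all of them from a seed, so the whole engine is exercisable with no external
data:

* a toy 3-sphere-ligand / 4-sphere-receptor matching system with known match
  counts at two tolerances;
* an *analytic field* — a handful of pseudo-receptor atoms with closed-form
  12-6 Lennard-Jones + Coulomb (relative dielectric 4) + Gaussian
  desolvation potentials — sampled onto grids;
* a *planted site*: grids and receptor spheres constructed around a known
  ligand pose, guaranteeing that pose is favourable and recoverable;
* score tables with ligand/decoy labels for metric testing;
* multi-conformer ring-containing ligand hierarchies.

Every generator is a pure function of its arguments (same seed, same bytes)
and asserts its own postconditions at build time.  The conformer-builder
settings the hierarchies emulate (0.4 A RMSD cutoff, up to 2000 conformers)
are recorded as metadata constants, not re-implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np

from .flexibase import Atom, Bond, ConformerHierarchy
from .grids import AtomScoreParams, BumpLimit, GridBundle, Lattice, PoseStatus, ScalarGrid, pose_energy
from .metrics import ScreenResult
from .spheres import SphereSet

__all__ = [
    "AnalyticField",
    "PseudoAtom",
    "make_fig1_system",
    "make_planted_site",
    "make_score_set",
    "make_hierarchy",
    "make_library",
    "invert_charges",
    "brute_force_matches",
]

# Emulated conformer-builder settings (metadata only; conformer generation
# itself is replaced by the deterministic geometry below).
BUILDER_RMSD_CUTOFF = 0.4  # A
BUILDER_MAX_CONFORMERS = 2000

COULOMB = 332.0636  # kcal A / (mol e^2)
DIELECTRIC = 4.0
CORE_RADIUS = 0.8  # A; pair potentials are clamped inside this radius


def brute_force_matches(lig: SphereSet, rec: SphereSet, tolerance: float,
                        node_count: int = 4) -> set[tuple[tuple[int, int], ...]]:
    """Literal enumeration over all subsets x injective assignments.

    Used for build-time self-verification of the toy matching system; the
    test suite carries its own copy so the check stays independent.
    """
    from .spheres import pairwise_distance_matrix

    dl = pairwise_distance_matrix(lig)
    dr = pairwise_distance_matrix(rec)
    found = set()
    for lsub in combinations(range(len(lig)), node_count):
        for rsub in permutations(range(len(rec)), node_count):
            ok = all(
                abs(dl[lsub[a], lsub[b]] - dr[rsub[a], rsub[b]]) <= tolerance
                for a, b in combinations(range(node_count), 2)
            )
            if ok:
                found.add(tuple(
                    (int(lig.indices[lsub[k]]), int(rec.indices[rsub[k]]))
                    for k in range(node_count)))
    return found


def make_fig1_system() -> tuple[SphereSet, SphereSet]:
    """Toy 3-sphere ligand and 4-sphere receptor with known match counts.

    The ligand is an exact 3-4-5 right triangle; the receptor is a perturbed
    3x4 rectangle, every corner triple of which is a near-3-4-5 triangle.
    The perturbations are sized so that 3-node matching finds exactly 2
    correspondences at tolerance 0.1 A, exactly 4 at 0.2 A and none at 0.
    Verified at build time by brute-force enumeration.
    """
    lig = SphereSet(np.array([
        [0.0, 0.0, 0.0],
        [3.0, 0.0, 0.0],
        [0.0, 4.0, 0.0],
    ]))
    rec = SphereSet(np.array([
        [0.0, 0.0, 0.0],
        [3.01, 0.0, 0.0],
        [3.11, 4.01, 0.0],
        [-0.0198, 4.0890, 0.0],
    ]))
    counts = {tol: len(brute_force_matches(lig, rec, tol, node_count=3))
              for tol in (0.0, 0.1, 0.2)}
    if counts != {0.0: 0, 0.1: 2, 0.2: 4}:  # pragma: no cover - construction invariant
        raise AssertionError(f"toy system self-check failed: {counts}")
    return lig, rec


# ---------------------------------------------------------------------------
# Analytic receptor fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudoAtom:
    position: np.ndarray
    sqrt_a: float = 0.0       # repulsive coefficient (receptor side)
    sqrt_b: float = 0.0       # attractive coefficient
    charge: float = 0.0       # e
    desolv_amplitude: float = 0.0


@dataclass(frozen=True)
class AnalyticField:
    """Closed-form pair potentials of a set of pseudo-receptor atoms."""

    atoms: tuple[PseudoAtom, ...]
    dielectric: float = DIELECTRIC
    core_radius: float = CORE_RADIUS
    desolv_sigma: float = 2.0

    def _r(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        pos = np.array([a.position for a in self.atoms])
        r = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
        return np.maximum(r, self.core_radius)

    def repulsive(self, points) -> np.ndarray:
        r = self._r(points)
        return (np.array([a.sqrt_a for a in self.atoms]) / r**12).sum(axis=1)

    def attractive(self, points) -> np.ndarray:
        r = self._r(points)
        return (np.array([a.sqrt_b for a in self.atoms]) / r**6).sum(axis=1)

    def potential(self, points) -> np.ndarray:
        r = self._r(points)
        q = np.array([a.charge for a in self.atoms])
        return (COULOMB * q / (self.dielectric * r)).sum(axis=1)

    def desolvation(self, points) -> np.ndarray:
        r = self._r(points)
        amp = np.array([a.desolv_amplitude for a in self.atoms])
        return np.clip((amp * np.exp(-(r**2) / (2 * self.desolv_sigma**2))).sum(axis=1),
                       0.0, 1.0)

    def sample(self, lattice: Lattice) -> GridBundle:
        """Sample the four potentials onto a shared lattice."""
        axes = [lattice.axis_points(i) for i in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        dims = lattice.dims
        return GridBundle(
            vdw_repulsive=ScalarGrid(lattice, self.repulsive(pts).reshape(dims),
                                     "vdw_repulsive", "sqrt(kcal/mol) A^-12 sum"),
            vdw_attractive=ScalarGrid(lattice, self.attractive(pts).reshape(dims),
                                      "vdw_attractive", "sqrt(kcal/mol) A^-6 sum"),
            electrostatic=ScalarGrid(lattice, self.potential(pts).reshape(dims),
                                     "electrostatic", "kcal/(mol e)"),
            desolvation=ScalarGrid(lattice, self.desolvation(pts).reshape(dims),
                                   "desolvation", "fraction"),
        )


# ---------------------------------------------------------------------------
# Ligand hierarchies
# ---------------------------------------------------------------------------

def make_hierarchy(n_atoms: int = 9, n_conformers: int = 3, n_hydroxyls: int = 0,
                   seed: int = 0, name: str | None = None) -> ConformerHierarchy:
    """Seeded ring-containing multi-conformer hierarchy.

    Geometry: a slightly irregular planar aromatic ring (6 heavy atoms, or 5
    when n_atoms == 5) — the rigid component — with an acyclic carbon tail
    whose rotation about its attachment bond generates the conformers, plus
    optional ring hydroxyls whose protons start ~1.2 rad out of plane so the
    rotamer-reset machinery has work to do.  Partial charges are seeded and
    sum to exactly zero.
    """
    if n_atoms < 5:
        raise ValueError("need at least 5 heavy atoms")
    rng = np.random.default_rng(seed)
    ring_size = 6 if n_atoms >= 6 else 5
    tail_len = n_atoms - ring_size
    if n_hydroxyls > ring_size - 1:
        raise ValueError("too many hydroxyls for the ring")

    atoms: list[Atom] = []
    bonds: list[Bond] = []
    coords: list[np.ndarray] = []

    # irregular planar ring (breaks rotational symmetry so self-matches are
    # only found at raised tolerances)
    radii = 1.4 + rng.uniform(-0.08, 0.08, size=ring_size)
    for k in range(ring_size):
        ang = 2 * math.pi * k / ring_size
        atoms.append(Atom(k, f"C{k + 1}", "C", "C.ar"))
        coords.append(np.array([radii[k] * math.cos(ang), radii[k] * math.sin(ang), 0.0]))
        bonds.append(Bond(k, (k + 1) % ring_size, "ar"))

    # tail grows from ring atom 0, zig-zag out of plane
    prev = 0
    direction = coords[0] / np.linalg.norm(coords[0])
    for t in range(tail_len):
        idx = len(atoms)
        atoms.append(Atom(idx, f"C{idx + 1}", "C", "C.3"))
        zig = np.array([0.0, 0.0, 0.45 if t % 2 == 0 else -0.45])
        coords.append(coords[prev] + direction * 1.45 + zig)
        bonds.append(Bond(prev, idx, "1"))
        prev = idx

    # hydroxyls on ring atoms 1, 2, ... with protons out of plane
    for h in range(n_hydroxyls):
        ring_atom = 1 + h
        o_idx = len(atoms)
        atoms.append(Atom(o_idx, f"O{h + 1}", "O", "O.3"))
        radial = coords[ring_atom] / np.linalg.norm(coords[ring_atom])
        coords.append(coords[ring_atom] + radial * 1.36)
        bonds.append(Bond(ring_atom, o_idx, "1"))
        h_idx = len(atoms)
        atoms.append(Atom(h_idx, f"H{h + 1}", "H", "H"))
        # proton ~1.2 rad out of the ring plane
        coords.append(coords[o_idx] + 0.35 * radial + np.array([0.0, 0.0, 0.89]))
        bonds.append(Bond(o_idx, h_idx, "1"))

    base = np.array(coords)

    # charges: seeded, zero total
    charges = np.round(rng.normal(0.0, 0.12, size=len(atoms)), 4)
    charges[0] = np.round(charges[0] - charges.sum(), 4)  # total charge exactly 0
    desolv = np.round(np.abs(rng.normal(0.2, 0.05, size=len(atoms))), 4)
    atoms = [
        Atom(a.index, a.name, a.element, a.mol2_type,
             float(charges[a.index]), a.mol2_type, float(desolv[a.index]))
        for a in atoms
    ]

    # conformers: rotate the tail about the ring-attachment direction
    conformers = []
    tail_idx = list(range(ring_size, ring_size + tail_len))
    for c in range(n_conformers):
        conf = base.copy()
        if tail_idx and c > 0:
            angle = c * 2 * math.pi / max(n_conformers, 2) * 0.7
            axis = direction
            pivot = base[0]
            for t in tail_idx:
                v = conf[t] - pivot
                cos, sin = math.cos(angle), math.sin(angle)
                conf[t] = pivot + v * cos + np.cross(axis, v) * sin \
                    + axis * (axis @ v) * (1 - cos)
        conformers.append(conf)
    energies = [0.0] + list(np.round(np.cumsum(rng.uniform(0.5, 3.0, size=max(n_conformers - 1, 0))), 4))

    mol = ConformerHierarchy(
        name=name or f"FIX{seed:04d}",
        atoms=atoms, bonds=bonds,
        conformers=conformers, conformer_energies=energies[:n_conformers],
    )
    assert set(range(ring_size)) <= set(mol.rigid_component), "ring must be rigid"
    return mol


def make_library(n_molecules: int = 20, seed: int = 0, **kwargs) -> list[ConformerHierarchy]:
    """A library of hierarchies with varied sizes, seeded reproducibly."""
    rng = np.random.default_rng(seed)
    mols = []
    for m in range(n_molecules):
        n_atoms = int(rng.integers(7, 13))
        n_conf = int(rng.integers(1, 4))
        mols.append(make_hierarchy(n_atoms=n_atoms, n_conformers=n_conf,
                                   seed=seed * 1000 + m + 1,
                                   name=f"LIB{seed:03d}_{m:03d}", **kwargs))
    return mols


def invert_charges(mol: ConformerHierarchy) -> ConformerHierarchy:
    """Charge-sign decoy: same geometry, negated partial charges."""
    atoms = [Atom(a.index, a.name, a.element, a.mol2_type, -a.partial_charge,
                  a.vdw_class, a.desolvation_energy) for a in mol.atoms]
    return ConformerHierarchy(
        name=mol.name + "_invq", atoms=atoms, bonds=mol.bonds,
        conformers=[c.copy() for c in mol.conformers],
        conformer_energies=list(mol.conformer_energies),
        rigid_component=list(mol.rigid_component),
    )


# ---------------------------------------------------------------------------
# Planted binding site
# ---------------------------------------------------------------------------

def make_planted_site(
    seed: int = 0,
    n_atoms: int = 9,
    n_conformers: int = 2,
    spacing: float = 0.4,
    margin: float = 4.0,
):
    """Grids + receptor spheres built around a known ligand pose.

    Pseudo-receptor atoms sit at the planted ligand's heavy-atom positions:
    attractive wells with mild repulsive cores, charges opposite to the
    ligand's own, and a shallow desolvation cloud.  Receptor spheres are the
    planted rigid-component heavy atoms (mirroring preparation pipelines that
    seed receptor spheres from crystallographic ligand atoms), so the
    identity correspondence exists at the lowest tolerance.

    Returns (bundle, receptor spheres, hierarchy, planted coordinates).
    Build-time checks: grids within 64^3, planted pose scores below -1
    kcal/mol and survives the default 50 kcal/mol bump limit.
    """
    mol = make_hierarchy(n_atoms=n_atoms, n_conformers=n_conformers, seed=seed,
                         name=f"PLANT{seed:04d}")
    planted = mol.conformers[0]
    heavy = [a.index for a in mol.atoms if a.is_heavy]

    pseudo = []
    for i in heavy:
        pseudo.append(PseudoAtom(
            position=planted[i].copy(),
            sqrt_a=2.0e-4,
            sqrt_b=0.05,
            charge=-2.0 * mol.atoms[i].partial_charge,
            desolv_amplitude=0.15,
        ))
    fld = AnalyticField(tuple(pseudo))

    lo = planted.min(axis=0) - margin
    hi = planted.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    if any(d > 64 for d in dims):  # pragma: no cover - documented bound
        raise ValueError(f"grid dims {dims} exceed the 64^3 fixture bound")
    lattice = Lattice(lo, spacing, dims)
    bundle = fld.sample(lattice)

    rigid = mol.rigid_heavy_indices
    rec_spheres = SphereSet(planted[rigid].copy())

    params = [AtomScoreParams(*a.sqrt_ab, a.partial_charge, a.desolvation_energy)
              for a in mol.atoms]
    total, _, status = pose_energy(planted, params, bundle, BumpLimit(50.0))
    if status is not PoseStatus.SCORED or total >= -1.0:  # pragma: no cover
        raise AssertionError(
            f"planted-site self-check failed: status={status}, total={total}")
    return bundle, rec_spheres, mol, planted.copy()


# ---------------------------------------------------------------------------
# Score sets for metric testing
# ---------------------------------------------------------------------------

def make_score_set(n_ligands: int, n_decoys: int, separation: float,
                   seed: int = 0) -> ScreenResult:
    """Gaussian score table: ligands ~ N(-separation, 1), decoys ~ N(0, 1)."""
    if n_ligands < 1 or n_decoys < 1:
        raise ValueError("need at least one ligand and one decoy")
    rng = np.random.default_rng(seed)
    scores = np.concatenate([
        rng.normal(-separation, 1.0, size=n_ligands),
        rng.normal(0.0, 1.0, size=n_decoys),
    ])
    labels = np.concatenate([
        np.ones(n_ligands, dtype=bool),
        np.zeros(n_decoys, dtype=bool),
    ])
    return ScreenResult(scores, labels)
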