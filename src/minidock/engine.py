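"""Docking orchestration: matching -> orientation -> scoring -> top-N poses.

For one molecule the ligand matching spheres are the heavy atoms of its rigid
component.  Correspondences against the receptor spheres come from the
adaptive matcher; each correspondence yields one rigid transform, which places
every conformer of the hierarchy at once (whole conformations only).  Each
(orientation, conformer) pair is scored on the grids with the bump filter, and
the best N surviving poses are kept in a bounded insertion-sorted list.

Everything is deterministic: orientations are scored in canonical match
order, conformers in file order, and ties in energy break on (orientation
index, conformer index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InputError
from .flexibase import ConformerHierarchy, write_mol2
from .grids import AtomScoreParams, BumpLimit, GridBundle, PoseStatus, pose_energy
from .matching import (
    Correspondence,
    MatchParams,
    MatchResult,
    RigidTransform,
    ToleranceSchedule,
    adaptive_match,
    fit_rigid_transform,
    orient_coordinates,
)
from .spheres import SphereSet

__all__ = ["Pose", "PoseList", "DockParams", "DockOutcome",
           "dock_molecule", "screen_library", "insert_pose", "poses_to_mol2"]

log = logging.getLogger(__name__)

NO_POSE_SENTINEL = 1000.0  # kcal/mol score reported for molecules with no pose


@dataclass(frozen=True)
class Pose:
    """One scored placement of one conformer."""

    molecule_id: str
    correspondence: Correspondence
    transform: RigidTransform
    orientation_index: int
    conformer_index: int
    coordinates: np.ndarray
    total: float
    breakdown: np.ndarray  # (n_atoms, 3): vdw, electrostatic, desolvation

    @property
    def terms(self) -> dict[str, float]:
        vdw, elec, desol = self.breakdown.sum(axis=0)
        return {"vdw": float(vdw), "electrostatic": float(elec),
                "desolvation": float(desol)}

    def sort_key(self):
        return (self.total, self.orientation_index, self.conformer_index)


class PoseList:
    """Bounded list of the best poses, kept sorted ascending by energy.

    Maintained by insertion sort; ties break on orientation then conformer
    index so repeated runs produce identical lists.
    """

    def __init__(self, capacity: int = 1):
        if capacity < 1:
            raise InputError("pose list capacity must be >= 1")
        self.capacity = capacity
        self.poses: list[Pose] = []

    def insert(self, pose: Pose) -> None:
        key = pose.sort_key()
        if len(self.poses) == self.capacity and key >= self.poses[-1].sort_key():
            return
        lo, hi = 0, len(self.poses)
        while lo < hi:
            mid = (lo + hi) // 2
            if self.poses[mid].sort_key() < key:
                lo = mid + 1
            else:
                hi = mid
        self.poses.insert(lo, pose)
        if len(self.poses) > self.capacity:
            self.poses.pop()

    @property
    def best(self) -> Pose | None:
        return self.poses[0] if self.poses else None

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


def insert_pose(pose_list: PoseList, pose: Pose) -> PoseList:
    """Functional wrapper over PoseList.insert (returns the same list)."""
    pose_list.insert(pose)
    return pose_list


@dataclass(frozen=True)
class DockParams:
    match: MatchParams = field(default_factory=MatchParams)
    schedule: ToleranceSchedule = field(default_factory=ToleranceSchedule)
    bump: BumpLimit = field(default_factory=BumpLimit)
    top_poses: int = 1

    def __post_init__(self):
        if self.top_poses < 1:
            raise InputError("top_poses must be >= 1")


@dataclass
class DockOutcome:
    """PoseList plus bookkeeping for one docked molecule."""

    molecule_id: str
    poses: PoseList
    match_result: MatchResult
    n_scored: int = 0
    n_bumped: int = 0
    n_out_of_grid: int = 0
    n_degenerate: int = 0
    n_conformers: int = 0
    error: str | None = None

    @property
    def status(self) -> str:
        if self.error:
            return "error"
        return "scored" if len(self.poses) else "no_pose"


def _atom_params(mol: ConformerHierarchy) -> list[AtomScoreParams]:
    out = []
    for a in mol.atoms:
        sa, sb = a.sqrt_ab
        out.append(AtomScoreParams(sqrt_a=sa, sqrt_b=sb, charge=a.partial_charge,
                                   desolvation_energy=a.desolvation_energy))
    return out


def dock_molecule(
    mol: ConformerHierarchy,
    rec_spheres: SphereSet,
    bundle: GridBundle,
    params: DockParams | None = None,
) -> DockOutcome:
    """Dock one hierarchy: returns its best poses and discard tallies."""
    params = params or DockParams()
    rigid = mol.rigid_heavy_indices
    if len(rigid) < params.match.node_count:
        raise InputError(
            f"{mol.name}: rigid component has {len(rigid)} heavy atoms, "
            f"need >= {params.match.node_count} for matching")
    lig_spheres = SphereSet(mol.conformers[0][rigid], np.array(rigid))
    match_result = adaptive_match(lig_spheres, rec_spheres, params.match, params.schedule)

    atom_params = _atom_params(mol)
    poses = PoseList(params.top_poses)
    outcome = DockOutcome(mol.name, poses, match_result, n_conformers=mol.n_conformers)

    for oi, corr in enumerate(match_result.correspondences):
        try:
            transform = fit_rigid_transform(corr, lig_spheres, rec_spheres)
        except DegenerateGeometryError:
            outcome.n_degenerate += 1
            continue
        for ci, conf in enumerate(mol.conformers):
            placed = orient_coordinates(transform, conf)
            total, breakdown, status = pose_energy(placed, atom_params, bundle, params.bump)
            if status is PoseStatus.BUMPED:
                outcome.n_bumped += 1
            elif status is PoseStatus.OUT_OF_GRID:
                outcome.n_out_of_grid += 1
            else:
                outcome.n_scored += 1
                poses.insert(Pose(
                    molecule_id=mol.name, correspondence=corr, transform=transform,
                    orientation_index=oi, conformer_index=ci,
                    coordinates=placed, total=total, breakdown=breakdown,
                ))
    if not len(poses):
        log.info("%s: no surviving pose (%d bumped, %d out of grid)",
                 mol.name, outcome.n_bumped, outcome.n_out_of_grid)
    return outcome


def screen_library(
    hierarchies: list[ConformerHierarchy],
    rec_spheres: SphereSet,
    bundle: GridBundle,
    params: DockParams | None = None,
) -> tuple[pd.DataFrame, list[DockOutcome]]:
    """Dock a library; returns the per-molecule score table and outcomes.

    Individual molecule failures are recorded in the table (status ``error``)
    and never abort the screen.  Row order follows input order; molecules are
    docked independently so results are invariant to library permutation.
    """
    if not hierarchies:
        raise InputError("empty library")
    params = params or DockParams()
    rows, outcomes = [], []
    for mol in hierarchies:
        try:
            outcome = dock_molecule(mol, rec_spheres, bundle, params)
        except Exception as exc:  # noqa: BLE001 - screens must survive
            log.warning("%s failed: %s", mol.name, exc)
            outcome = DockOutcome(mol.name, PoseList(params.top_poses),
                                  MatchResult((), 0.0, False), error=str(exc))
        outcomes.append(outcome)
        best = outcome.poses.best
        terms = best.terms if best else {}
        rows.append({
            "molecule_id": outcome.molecule_id,
            "status": outcome.status,
            "total": best.total if best else NO_POSE_SENTINEL,
            "vdw": terms.get("vdw", NO_POSE_SENTINEL),
            "electrostatic": terms.get("electrostatic", NO_POSE_SENTINEL),
            "desolvation": terms.get("desolvation", NO_POSE_SENTINEL),
            "n_orientations": len(outcome.match_result.correspondences),
            "n_conformers_scored": outcome.n_scored,
        })
    return pd.DataFrame(rows), outcomes


def write_score_table(table: pd.DataFrame, path) -> None:
    """TSV with fixed float formatting so identical runs are byte-identical."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def poses_to_mol2(mol: ConformerHierarchy, poses: PoseList,
                  per_atom_breakdown: bool = False) -> str:
    """Render poses as a multi-MOLECULE mol2 block with score comments."""
    posed = ConformerHierarchy(
        name=mol.name, atoms=mol.atoms, bonds=mol.bonds,
        conformers=[p.coordinates for p in poses],
        conformer_energies=[mol.conformer_energies[p.conformer_index] for p in poses],
        rigid_component=[],  # posed coordinates are no longer a shared frame
    )
    comments = []
    for p in poses:
        t = p.terms
        lines = [
            f"pose orientation={p.orientation_index} conformer={p.conformer_index}",
            f"score total={p.total:.6f} vdw={t['vdw']:.6f} "
            f"electrostatic={t['electrostatic']:.6f} desolvation={t['desolvation']:.6f}",
        ]
        if per_atom_breakdown:
            for a, (vdw, elec, desol) in zip(mol.atoms, p.breakdown):
                lines.append(f"atom_score {a.index} {a.name} "
                             f"{vdw:.6f} {elec:.6f} {desol:.6f}")
        comments.append(lines)
    return write_mol2(posed, comments=comments)
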