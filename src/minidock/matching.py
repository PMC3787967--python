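"""Clique-based orientation matching with an adaptive distance tolerance.

A *correspondence* maps ``node_count`` ligand spheres onto as many receptor
spheres such that every internal distance agrees between the two sides within
a tolerance (for the standard 4 nodes that is all C(4,2) = 6 distances — the
edges of a tetrahedron).  Enumeration is complete over all subsets and
injective assignments, so sampling is deterministic and strictly monotone in
the tolerance: every match found at a lower tolerance is found again at any
higher one.

The adaptive driver escalates the tolerance along a fixed schedule (start low,
default 0.05 A, grow slowly) until a desired number of matches — the *match
goal* — is reached.  A single parameter thus controls how many orientations
are sampled, and a larger goal always yields a superset of the orientations
found with a smaller one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DegenerateGeometryError, InputError
from .spheres import SphereSet, pairwise_distance_matrix

__all__ = [
    "Correspondence",
    "ToleranceSchedule",
    "MatchParams",
    "MatchResult",
    "RigidTransform",
    "enumerate_matches",
    "adaptive_match",
    "fit_rigid_transform",
    "orient_coordinates",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Correspondence:
    """Ordered (ligand index, receptor index) pairs defining one orientation."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def ligand_indices(self) -> tuple[int, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def receptor_indices(self) -> tuple[int, ...]:
        return tuple(p[1] for p in self.pairs)


@dataclass(frozen=True)
class ToleranceSchedule:
    """Distance-tolerance escalation schedule (Angstroms).

    Defaults start very low (0.05 A) and grow slowly so that the match goal,
    not the tolerance, controls a run.
    """

    minimum: float = 0.05
    increment: float = 0.05
    maximum: float = 1.5

    def __post_init__(self):
        if not (0 < self.minimum <= self.maximum) or self.increment <= 0:
            raise InputError("invalid tolerance schedule")

    def steps(self):
        """Yield minimum, minimum+increment, ... up to and including maximum."""
        k = 0
        while True:
            t = self.minimum + k * self.increment
            if t > self.maximum + 1e-12:
                return
            yield min(t, self.maximum)
            k += 1


@dataclass(frozen=True)
class MatchParams:
    match_goal: int = 500
    node_count: int = 4

    def __post_init__(self):
        if self.match_goal < 1:
            raise InputError("match_goal must be >= 1")
        if self.node_count < 3:
            raise InputError("node_count must be >= 3")


@dataclass(frozen=True)
class MatchResult:
    correspondences: tuple[Correspondence, ...]
    tolerance: float
    goal_met: bool


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x' = R x + t with its least-squares residual."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float


def comparisons_per_candidate(node_count: int = 4) -> int:
    """Distance comparisons needed to accept one full candidate clique."""
    return math.comb(node_count, 2)


def enumerate_matches(
    lig: SphereSet,
    rec: SphereSet,
    tolerance: float,
    node_count: int = 4,
    stats: dict | None = None,
) -> list[Correspondence]:
    """Enumerate every correspondence whose distance differences are all <= tolerance.

    Complete over all ``node_count``-subsets of ligand spheres crossed with all
    injective receptor assignments, returned in canonical order: lexicographic
    by the sorted ligand index tuple, then by the receptor index tuple.  A
    backtracking search prunes partial assignments, but accepted candidates
    always consume exactly C(node_count, 2) distance comparisons on their
    accepting path.

    ``stats`` (optional dict) receives ``comparisons`` (total distance checks)
    and ``candidate_comparison_counts`` (checks on each accepting path).
    """
    if tolerance < 0:
        raise InputError("tolerance must be >= 0")
    nl, nr = len(lig), len(rec)
    if nl < node_count or nr < node_count:
        log.info("too few spheres to match (%d ligand, %d receptor, need %d)", nl, nr, node_count)
        return []
    dl = pairwise_distance_matrix(lig)
    dr = pairwise_distance_matrix(rec)
    results: list[Correspondence] = []
    comparisons = 0
    per_candidate: list[int] = []
    rec_range = range(nr)

    for lig_subset in combinations(range(nl), node_count):
        assign: list[int] = []
        used = [False] * nr

        def extend(depth: int, path_cost: int):
            nonlocal comparisons
            if depth == node_count:
                per_candidate.append(path_cost)
                pairs = tuple(
                    (int(lig.indices[lig_subset[k]]), int(rec.indices[assign[k]]))
                    for k in range(node_count)
                )
                results.append(Correspondence(pairs))
                return
            li = lig_subset[depth]
            for r in rec_range:
                if used[r]:
                    continue
                ok = True
                cost = 0
                for k in range(depth):
                    cost += 1
                    if abs(dl[li, lig_subset[k]] - dr[r, assign[k]]) > tolerance:
                        ok = False
                        break
                comparisons += cost
                if ok:
                    used[r] = True
                    assign.append(r)
                    extend(depth + 1, path_cost + cost)
                    assign.pop()
                    used[r] = False

        extend(0, 0)

    if stats is not None:
        stats["comparisons"] = comparisons
        stats["candidate_comparison_counts"] = per_candidate
    return results


def adaptive_match(
    lig: SphereSet,
    rec: SphereSet,
    params: MatchParams | None = None,
    schedule: ToleranceSchedule | None = None,
) -> MatchResult:
    """Escalate the distance tolerance until the match goal is reached.

    Iterates tolerance = minimum, minimum + increment, ... and stops at the
    first tolerance yielding at least ``match_goal`` correspondences, or at
    ``maximum`` with a warning flag if the goal is unreachable.  All matches
    found at the final tolerance are returned, never truncated to the goal, so
    the result at a larger goal is always a superset of a smaller one.
    """
    params = params or MatchParams()
    schedule = schedule or ToleranceSchedule()
    matches: list[Correspondence] = []
    tol = schedule.minimum
    for tol in schedule.steps():
        matches = enumerate_matches(lig, rec, tol, params.node_count)
        if len(matches) >= params.match_goal:
            return MatchResult(tuple(matches), tol, True)
    log.warning(
        "match goal %d unreachable: %d matches at maximum tolerance %.3f A",
        params.match_goal, len(matches), tol,
    )
    return MatchResult(tuple(matches), tol, False)


def fit_rigid_transform(
    correspondence: Correspondence, lig: SphereSet, rec: SphereSet
) -> RigidTransform:
    """Least-squares superposition of matched ligand spheres onto receptor spheres.

    Kabsch algorithm via SVD, restricted to proper rotations (det = +1);
    reflections are rejected because docking a mirror image is unphysical.

    Raises
    ------
    DegenerateGeometryError
        If the matched ligand points are (near-)collinear — singular-value
        ratio below 1e-6 — so no orientation is defined.
    """
    lig_pos = {int(i): c for i, c in zip(lig.indices, lig.coords)}
    rec_pos = {int(i): c for i, c in zip(rec.indices, rec.coords)}
    p = np.array([lig_pos[i] for i, _ in correspondence.pairs])
    q = np.array([rec_pos[j] for _, j in correspondence.pairs])
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc

    spread = np.linalg.svd(p0, compute_uv=False)
    if spread[0] <= 0 or spread[1] / spread[0] < 1e-6:
        raise DegenerateGeometryError("matched spheres are collinear; correspondence discarded")

    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    residual = float(np.sqrt(np.mean(np.sum((p @ rot.T + trans - q) ** 2, axis=1))))
    return RigidTransform(rot, trans, residual)


def orient_coordinates(transform: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Apply x' = R x + t to an (n, 3) coordinate block."""
    coords = np.asarray(coords, dtype=float)
    return coords @ transform.rotation.T + transform.translation
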