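"""Virtual-screening evaluation metrics.

Enrichment of known ligands over property-matched decoys is summarised three
ways: the area under the ROC curve (AUC), the enrichment factor at the top 1%
of the ranked list (EF1), and the *adjusted logAUC* — the area under the ROC
curve drawn with a logarithmic false-positive axis (lower bound lambda =
0.001), minus the area a random classifier would attain, so that zero means
random enrichment and positive values mean early enrichment of ligands.

Pose geometry is judged by symmetry-corrected RMSD: heavy atoms are assigned
between reference and probe by a minimum-cost perfect matching restricted to
identical elements (Kuhn-Munkres / Hungarian algorithm), so topologically
equivalent atoms — e.g. the two carboxylate oxygens — cannot inflate the
deviation.  The *critical-contact* variant matches a handful of
pharmacophore-defining reference atoms to any pose atoms of the same element;
when a pose lacks the required elements its RMSD is undefined (not zero), and
library-level aggregation therefore uses the median over defined values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InputError, MetricError

__all__ = [
    "ScreenResult",
    "roc_points",
    "auc",
    "ef",
    "log_auc",
    "adjusted_log_auc",
    "random_log_auc",
    "hungarian_rmsd",
    "critical_contact_rmsd",
    "median_defined",
    "EnrichmentStats",
    "enrichment_stats",
]

LAMBDA_DEFAULT = 0.001


@dataclass(frozen=True)
class ScreenResult:
    """Per-molecule docking scores (lower = better) with ligand/decoy labels."""

    scores: np.ndarray
    is_ligand: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.is_ligand, dtype=bool)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise InputError("scores and labels must be equal-length 1-D arrays")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "is_ligand", labels)

    @property
    def n_ligands(self) -> int:
        return int(self.is_ligand.sum())

    @property
    def n_decoys(self) -> int:
        return int((~self.is_ligand).sum())


def roc_points(result: ScreenResult) -> np.ndarray:
    """(FPR, TPR) vertices of the ROC curve, ranked best (lowest) score first.

    Tied scores are collapsed into a single segment, so the trapezoidal area
    through a tie block equals the average over all orderings of the ties.
    Returns an (m, 2) array from (0, 0) to (1, 1).
    """
    if result.n_ligands == 0 or result.n_decoys == 0:
        raise MetricError("ROC needs at least one ligand and one decoy")
    order = np.argsort(result.scores, kind="stable")
    scores = result.scores[order]
    labels = result.is_ligand[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        block = labels[i:j]
        tp += int(block.sum())
        fp += int((~block).sum())
        points.append((fp / result.n_decoys, tp / result.n_ligands))
        i = j
    return np.array(points)


def auc(curve: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve (0-1 fraction)."""
    curve = np.asarray(curve, dtype=float)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def ef(result: ScreenResult, fraction: float = 0.01) -> float:
    """Enrichment factor at the top ``fraction`` of the ranked list.

    EF_f = (fraction of all ligands ranked within the top ceil(f*N)) / f.
    Ties are broken by input order (stable sort).
    """
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    n = len(result.scores)
    if fraction * n < 1:
        raise MetricError(
            f"top {fraction:.2%} of {n} compounds is less than one molecule; "
            "use a larger screen")
    if result.n_ligands == 0 or result.n_decoys == 0:
        raise MetricError("EF needs at least one ligand and one decoy")
    top = math.ceil(fraction * n)
    order = np.argsort(result.scores, kind="stable")
    found = int(result.is_ligand[order[:top]].sum())
    return (found / result.n_ligands) / fraction


def _tpr_at(curve: np.ndarray, fpr: float) -> float:
    """Linear interpolation of TPR at a given FPR along the curve."""
    f, t = curve[:, 0], curve[:, 1]
    return float(np.interp(fpr, f, t))


def log_auc(curve: np.ndarray, lambda_min: float = LAMBDA_DEFAULT) -> float:
    """Semilog AUC in percent: integral of TPR d(log10 FPR) over [lambda, 1],
    normalised by log10(1/lambda).

    The curve is piecewise linear in (FPR, TPR); each segment is integrated
    against d(log10 FPR) in closed form, which reduces to the trapezoid rule
    on the axis-parallel segments of a staircase ROC and is exact on tie
    diagonals.
    """
    curve = np.asarray(curve, dtype=float)
    lam = lambda_min
    if not 0 < lam < 1:
        raise InputError("lambda_min must be in (0, 1)")
    t_lam = _tpr_at(curve, lam)
    keep = curve[curve[:, 0] > lam]
    vertices = np.vstack([[lam, t_lam], keep]) if len(keep) else np.array([[lam, t_lam], [1.0, 1.0]])
    total = 0.0
    for (f1, t1), (f2, t2) in zip(vertices[:-1], vertices[1:]):
        if f2 <= f1:
            continue
        b = (t2 - t1) / (f2 - f1)
        total += (t1 - b * f1) * math.log(f2 / f1) + b * (f2 - f1)
    total /= math.log(10.0)
    return 100.0 * total / math.log10(1.0 / lam)


def random_log_auc(lambda_min: float = LAMBDA_DEFAULT) -> float:
    """Semilog AUC (percent) of the random classifier TPR = FPR."""
    lam = lambda_min
    return 100.0 * (1.0 - lam) / math.log(1.0 / lam)


def adjusted_log_auc(curve: np.ndarray, lambda_min: float = LAMBDA_DEFAULT) -> float:
    """logAUC minus the random-classifier reference, in percent.

    Zero represents random enrichment; positive values, early enrichment.
    """
    return log_auc(curve, lambda_min) - random_log_auc(lambda_min)


@dataclass(frozen=True)
class EnrichmentStats:
    auc: float
    log_auc: float
    adjusted_log_auc: float
    ef1: float


def enrichment_stats(result: ScreenResult, lambda_min: float = LAMBDA_DEFAULT,
                     ef_fraction: float = 0.01) -> EnrichmentStats:
    curve = roc_points(result)
    la = log_auc(curve, lambda_min)
    return EnrichmentStats(
        auc=auc(curve),
        log_auc=la,
        adjusted_log_auc=la - random_log_auc(lambda_min),
        ef1=ef(result, ef_fraction),
    )


# ---------------------------------------------------------------------------
# Symmetry-corrected RMSD
# ---------------------------------------------------------------------------

def hungarian_rmsd(ref_elements, ref_coords, probe_elements, probe_coords) -> float:
    """Heavy-atom RMSD under the optimal same-element assignment.

    Minimum-cost perfect matching (Kuhn-Munkres) restricted to pairs of
    identical elements, cost = squared distance.  The element multisets of
    the two structures must agree.
    """
    ref_coords = np.asarray(ref_coords, dtype=float)
    probe_coords = np.asarray(probe_coords, dtype=float)
    ref_elements = [e.upper() for e in ref_elements]
    probe_elements = [e.upper() for e in probe_elements]
    ref_heavy = [i for i, e in enumerate(ref_elements) if e != "H"]
    probe_heavy = [i for i, e in enumerate(probe_elements) if e != "H"]
    if sorted(ref_elements[i] for i in ref_heavy) != sorted(probe_elements[i] for i in probe_heavy):
        raise MetricError("heavy-atom element multisets differ")
    total_sq = 0.0
    n = 0
    for elem in sorted(set(ref_elements[i] for i in ref_heavy)):
        ri = [i for i in ref_heavy if ref_elements[i] == elem]
        pi = [i for i in probe_heavy if probe_elements[i] == elem]
        cost = np.sum(
            (ref_coords[ri][:, None, :] - probe_coords[pi][None, :, :]) ** 2, axis=2)
        rows, cols = linear_sum_assignment(cost)
        total_sq += float(cost[rows, cols].sum())
        n += len(ri)
    return math.sqrt(total_sq / n)


def critical_contact_rmsd(critical_elements, critical_coords,
                          pose_elements, pose_coords) -> float | None:
    """RMSD of a small critical-contact atom set against any same-element pose atoms.

    Each critical reference atom is assigned (optimally, Kuhn-Munkres on the
    rectangular cost matrix) to a distinct pose atom of the same element.
    Returns None — undefined, not zero — when the pose lacks enough atoms of
    a required element; undefined values are excluded from medians.
    """
    if len(critical_elements) == 0:
        raise MetricError("empty critical-contact set")
    critical_coords = np.asarray(critical_coords, dtype=float)
    pose_coords = np.asarray(pose_coords, dtype=float)
    critical_elements = [e.upper() for e in critical_elements]
    pose_elements = [e.upper() for e in pose_elements]
    total_sq = 0.0
    n = 0
    for elem in sorted(set(critical_elements)):
        ci = [i for i, e in enumerate(critical_elements) if e == elem]
        pi = [i for i, e in enumerate(pose_elements) if e == elem]
        if len(pi) < len(ci):
            return None
        cost = np.sum(
            (critical_coords[ci][:, None, :] - pose_coords[pi][None, :, :]) ** 2, axis=2)
        rows, cols = linear_sum_assignment(cost)
        total_sq += float(cost[rows, cols].sum())
        n += len(ci)
    return math.sqrt(total_sq / n)


def median_defined(values) -> float | None:
    """Median over defined (non-None, finite) values; None if none are defined."""
    defined = [v for v in values if v is not None and math.isfinite(v)]
    if not defined:
        return None
    return float(np.median(defined))
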