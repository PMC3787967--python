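"""Matching spheres: labelled 3-D points used to generate ligand orientations.

On the receptor side a sphere marks a "hot-spot" where a ligand heavy atom is
likely to sit; on the ligand side spheres are the heavy-atom positions of the
rigid component.  Sphere sets carry stable integer indices so that
correspondences between the two sides are reproducible.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParseError

__all__ = ["SphereSet", "pairwise_distance_matrix", "read_sphere_file", "write_sphere_file"]


@dataclass(frozen=True)
class SphereSet:
    """A set of labelled spheres.

    Parameters
    ----------
    coords
        (n, 3) array of positions in Angstroms.
    indices
        Stable 0-based integer labels, one per sphere.  Defaults to 0..n-1.
    """

    coords: np.ndarray
    indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"sphere coordinates must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise InputError("sphere coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if self.indices is None:
            idx = np.arange(len(coords))
        else:
            idx = np.asarray(self.indices, dtype=int)
        if len(idx) != len(coords) or len(np.unique(idx)) != len(idx):
            raise InputError("sphere indices must be unique and match coordinate count")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.coords)


def pairwise_distance_matrix(spheres: SphereSet | np.ndarray) -> np.ndarray:
    """Full symmetric Euclidean distance matrix of a sphere set (Angstroms).

    The full matrix (rather than a binned histogram of distances) is what makes
    clique matching exact and deterministic.
    """
    coords = spheres.coords if isinstance(spheres, SphereSet) else np.asarray(spheres, float)
    if len(coords) < 1:
        raise InputError("need at least one sphere")
    if not np.all(np.isfinite(coords)):
        raise InputError("non-finite coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


_SPH_LINE = re.compile(r"^\s*(\d+)\s+(-?[\d.eE+-]+)\s+(-?[\d.eE+-]+)\s+(-?[\d.eE+-]+)")


def read_sphere_file(stream) -> SphereSet:
    """Read a sphere file.

    Canonical dialect: one sphere per line, ``index x y z`` with free-format
    floats, ``#`` comments and blank lines ignored.  Lines in the classic
    SPHGEN fixed-width layout (index in columns 1-5, coordinates in 10.5f
    fields) are also accepted since they match the same token pattern.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    indices, coords = [], []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _SPH_LINE.match(line)
        if not m:
            raise ParseError(f"cannot parse sphere line: {raw.rstrip()!r}", line=lineno)
        indices.append(int(m.group(1)))
        coords.append([float(m.group(2)), float(m.group(3)), float(m.group(4))])
    if not coords:
        raise ParseError("sphere file contains no spheres")
    return SphereSet(np.array(coords), np.array(indices))


def write_sphere_file(spheres: SphereSet, stream=None) -> str:
    """Write the canonical plain-text sphere dialect; returns the text."""
    lines = ["# minidock sphere file: index x y z (Angstroms)"]
    for i, (x, y, z) in zip(spheres.indices, spheres.coords):
        lines.append(f"{i} {x:.6f} {y:.6f} {z:.6f}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text
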