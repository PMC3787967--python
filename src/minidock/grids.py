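"""Regular-lattice energy grids, trilinear interpolation and pose scoring.

The receptor is represented by four co-registered scalar lattices:

* ``vdw_repulsive`` — sum over receptor atoms of sqrt(A_k) / r^12
* ``vdw_attractive`` — sum of sqrt(B_k) / r^6
* ``electrostatic`` — potential in kcal/(mol.e)
* ``desolvation`` — dimensionless fractional desolvation

A ligand atom's energy is read off the grids with trilinear interpolation and
multiplied by the atom's own properties (its sqrt(A)/sqrt(B) coefficients in
the geometric-combination convention, partial charge, and per-atom transfer
free energy):

    E_atom = sqrt(a) R(x) - sqrt(b) A(x) + q Phi(x) + dE_solv D(x)

Interpolation has two code paths: a straightforward 8-corner blend, and a
precomputed path that stores the 8 corner values of every interpolation cube
contiguously so scoring needs no strided gathers.  The two are required to
agree; the precomputed path costs roughly 8x the grid memory.

Scoring accumulates a running sum of the (always non-negative) repulsive vdW
contributions; once it exceeds the *bump limit* the pose is certain to be
sterically unrealistic and evaluation stops early.  Atoms falling off the
lattice reject the pose outright — grids are trimmed to the region where
scores are meaningful and nothing is extrapolated.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import InputError, OutOfGridError, ParseError

__all__ = [
    "Lattice",
    "ScalarGrid",
    "PrecomputedGrid",
    "GridBundle",
    "AtomScoreParams",
    "BumpLimit",
    "PoseStatus",
    "trilinear_naive",
    "precompute",
    "atom_energy",
    "pose_energy",
    "read_grid",
    "write_grid",
]

GRID_KINDS = ("vdw_repulsive", "vdw_attractive", "electrostatic", "desolvation")


@dataclass(frozen=True)
class Lattice:
    """Uniform axis-aligned lattice: origin (A), spacing (A), point counts."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.spacing <= 0:
            raise InputError("lattice spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise InputError("lattice needs >= 2 points per axis")

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.dims) - 1)

    def axis_points(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.dims[axis])


@dataclass(frozen=True)
class ScalarGrid:
    lattice: Lattice
    values: np.ndarray
    kind: str = "generic"
    units: str = ""

    def __post_init__(self):
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        if vals.shape != self.lattice.dims:
            raise InputError(f"grid shape {vals.shape} != lattice dims {self.lattice.dims}")
        if not np.all(np.isfinite(vals)):
            raise InputError("grid values must be finite")
        object.__setattr__(self, "values", vals)


class PrecomputedGrid:
    """Per-cube interpolation table: the 8 corner values of every cube, contiguous.

    ``corners`` has shape (nx-1, ny-1, nz-1, 8) with corner order
    (dx, dy, dz) in bit order dz + 2*dy + 4*dx, matching `trilinear_naive`.
    Reconstructs the source grid exactly at lattice points.
    """

    def __init__(self, grid: ScalarGrid):
        self.lattice = grid.lattice
        v = grid.values
        c = np.empty((v.shape[0] - 1, v.shape[1] - 1, v.shape[2] - 1, 8))
        for bit in range(8):
            dx, dy, dz = (bit >> 2) & 1, (bit >> 1) & 1, bit & 1
            c[..., bit] = v[dx : v.shape[0] - 1 + dx,
                            dy : v.shape[1] - 1 + dy,
                            dz : v.shape[2] - 1 + dz]
        self.corners = np.ascontiguousarray(c)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Vectorised trilinear interpolation of (n, 3) points (A).

        Raises OutOfGridError if any point leaves the lattice box.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        lat = self.lattice
        f = (points - lat.origin) / lat.spacing
        n = np.array(lat.dims)
        if np.any(f < -1e-9) or np.any(f > n - 1 + 1e-9):
            raise OutOfGridError("point outside lattice")
        cell = np.clip(np.floor(f).astype(int), 0, n - 2)
        t = f - cell
        cube = self.corners[cell[:, 0], cell[:, 1], cell[:, 2]]  # (n, 8)
        wx = np.stack([1 - t[:, 0], t[:, 0]], axis=1)
        wy = np.stack([1 - t[:, 1], t[:, 1]], axis=1)
        wz = np.stack([1 - t[:, 2], t[:, 2]], axis=1)
        w = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 8)
        return np.einsum("ij,ij->i", cube, w)


def trilinear_naive(grid: ScalarGrid, point) -> float:
    """Reference 8-corner trilinear blend at a single point (A)."""
    lat = grid.lattice
    f = (np.asarray(point, dtype=float) - lat.origin) / lat.spacing
    n = np.array(lat.dims)
    if np.any(f < -1e-9) or np.any(f > n - 1 + 1e-9):
        raise OutOfGridError(f"point {point} outside lattice")
    i = np.clip(np.floor(f).astype(int), 0, n - 2)
    tx, ty, tz = f - i
    v = grid.values
    out = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((tx if dx else 1 - tx)
                     * (ty if dy else 1 - ty)
                     * (tz if dz else 1 - tz))
                out += w * v[i[0] + dx, i[1] + dy, i[2] + dz]
    return float(out)


def precompute(grid: ScalarGrid) -> PrecomputedGrid:
    """Build the contiguous per-cube corner table for fast interpolation."""
    return PrecomputedGrid(grid)


@dataclass
class GridBundle:
    """The four co-registered receptor grids, with lazy fast-path tables."""

    vdw_repulsive: ScalarGrid
    vdw_attractive: ScalarGrid
    electrostatic: ScalarGrid
    desolvation: ScalarGrid
    electrostatic_scale: float = 1.0  # unit conversion hook for imported grids

    def __post_init__(self):
        lat = self.vdw_repulsive.lattice
        for kind in GRID_KINDS[1:]:
            g = getattr(self, kind)
            if g.lattice.dims != lat.dims or g.lattice.spacing != lat.spacing or \
               not np.allclose(g.lattice.origin, lat.origin):
                raise InputError("all grids in a bundle must share one lattice")
        self._fast: dict[str, PrecomputedGrid] = {}

    @property
    def lattice(self) -> Lattice:
        return self.vdw_repulsive.lattice

    def fast(self, kind: str) -> PrecomputedGrid:
        if kind not in self._fast:
            self._fast[kind] = precompute(getattr(self, kind))
        return self._fast[kind]


@dataclass(frozen=True)
class AtomScoreParams:
    """Per-atom scoring properties multiplied into the grid potentials."""

    sqrt_a: float = 0.0
    sqrt_b: float = 0.0
    charge: float = 0.0
    desolvation_energy: float = 0.0

    def __post_init__(self):
        if self.sqrt_a < 0 or self.sqrt_b < 0:
            raise InputError("vdW coefficients must be >= 0")


@dataclass(frozen=True)
class BumpLimit:
    """Repulsive-vdW rejection threshold in kcal/mol; None means no limit."""

    limit: float | None = 50.0

    def __post_init__(self):
        if self.limit is not None and self.limit <= 0:
            raise InputError("finite bump limit must be > 0")

    @property
    def value(self) -> float:
        return np.inf if self.limit is None else self.limit


class PoseStatus(Enum):
    SCORED = "scored"
    BUMPED = "bumped"
    OUT_OF_GRID = "out_of_grid"


def atom_energy(params: AtomScoreParams, point, bundle: GridBundle):
    """Per-term energies (vdw, electrostatic, desolvation; kcal/mol) and total."""
    pt = np.atleast_2d(np.asarray(point, dtype=float))
    rep = bundle.fast("vdw_repulsive").interpolate(pt)[0]
    att = bundle.fast("vdw_attractive").interpolate(pt)[0]
    phi = bundle.fast("electrostatic").interpolate(pt)[0] * bundle.electrostatic_scale
    dsv = bundle.fast("desolvation").interpolate(pt)[0]
    vdw = params.sqrt_a * rep - params.sqrt_b * att
    elec = params.charge * phi
    desol = params.desolvation_energy * dsv
    return {"vdw": vdw, "electrostatic": elec, "desolvation": desol,
            "total": vdw + elec + desol}


def pose_energy(
    coords: np.ndarray,
    params: list[AtomScoreParams],
    bundle: GridBundle,
    bump: BumpLimit = BumpLimit(),
):
    """Score one pose: per-atom, per-term breakdown with bump-filter early exit.

    Returns ``(total, breakdown, status)`` where ``breakdown`` is an
    (n_atoms, 3) array of (vdw, electrostatic, desolvation) terms.  The
    running sum of repulsive vdW contributions (accumulated in atom order) is
    compared to the bump limit; on exceeding it the pose is rejected with
    status BUMPED and no total.  Any atom off the lattice gives OUT_OF_GRID.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) != len(params):
        raise InputError(f"{len(coords)} coordinates but {len(params)} atom parameter sets")
    if not np.all(np.isfinite(coords)):
        raise InputError("non-finite pose coordinates")
    sqrt_a = np.array([p.sqrt_a for p in params])
    sqrt_b = np.array([p.sqrt_b for p in params])
    charge = np.array([p.charge for p in params])
    dsv_e = np.array([p.desolvation_energy for p in params])
    try:
        rep = bundle.fast("vdw_repulsive").interpolate(coords)
        att = bundle.fast("vdw_attractive").interpolate(coords)
        phi = bundle.fast("electrostatic").interpolate(coords) * bundle.electrostatic_scale
        dsv = bundle.fast("desolvation").interpolate(coords)
    except OutOfGridError:
        return None, None, PoseStatus.OUT_OF_GRID

    repulsive_terms = sqrt_a * rep  # >= 0 by construction
    if np.any(np.cumsum(repulsive_terms) > bump.value):
        return None, None, PoseStatus.BUMPED

    breakdown = np.column_stack([
        repulsive_terms - sqrt_b * att,
        charge * phi,
        dsv_e * dsv,
    ])
    total = float(breakdown.sum())
    return total, breakdown, PoseStatus.SCORED


# ---------------------------------------------------------------------------
# Grid file I/O.  Documented header + values in x-fastest order; text and raw
# little-endian float64 binary variants, both gzip-transparent.
# ---------------------------------------------------------------------------

_MAGIC = "# minidock grid 1"


def write_grid(grid: ScalarGrid, path, binary: bool = False) -> None:
    path = Path(path)
    lat = grid.lattice
    header = (
        f"{_MAGIC}\n"
        f"kind {grid.kind}\n"
        f"units {grid.units or '-'}\n"
        f"origin {lat.origin[0]:.8g} {lat.origin[1]:.8g} {lat.origin[2]:.8g}\n"
        f"spacing {lat.spacing:.8g}\n"
        f"dims {lat.dims[0]} {lat.dims[1]} {lat.dims[2]}\n"
        f"encoding {'binary' if binary else 'text'}\n"
    )
    opener = gzip.open if path.suffix == ".gz" else open
    # values in x-fastest order: transpose so x varies quickest in C order
    flat = grid.values.transpose(2, 1, 0).ravel()
    with opener(path, "wb") as fh:
        fh.write(header.encode())
        if binary:
            fh.write(flat.astype("<f8").tobytes())
        else:
            body = "\n".join(f"{v:.17g}" for v in flat) + "\n"
            fh.write(body.encode())


def read_grid(path) -> ScalarGrid:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        data = fh.read()
    lines = data.split(b"\n", 7)
    if not lines[0].decode(errors="replace").startswith("# minidock grid"):
        raise ParseError(f"{path}: not a minidock grid file", line=1)
    meta = {}
    for i, ln in enumerate(lines[1:7], start=2):
        try:
            key, _, rest = ln.decode().partition(" ")
        except UnicodeDecodeError as e:
            raise ParseError(f"{path}: bad header", line=i) from e
        meta[key] = rest
    try:
        origin = [float(x) for x in meta["origin"].split()]
        spacing = float(meta["spacing"])
        dims = tuple(int(x) for x in meta["dims"].split())
        encoding = meta["encoding"]
    except (KeyError, ValueError) as e:
        raise ParseError(f"{path}: malformed grid header: {e}") from e
    lat = Lattice(np.array(origin), spacing, dims)
    n = dims[0] * dims[1] * dims[2]
    body = lines[7]
    if encoding == "binary":
        flat = np.frombuffer(body[: 8 * n], dtype="<f8").astype(float)
    else:
        flat = np.array(body.decode().split(), dtype=float)
    if flat.size != n:
        raise ParseError(f"{path}: expected {n} values, found {flat.size}")
    values = flat.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    units = meta.get("units", "-")
    return ScalarGrid(lat, values, kind=meta.get("kind", "generic"),
                      units="" if units == "-" else units)


def write_bundle(bundle: GridBundle, directory) -> None:
    """Write the four grids of a bundle as ``<kind>.grid`` files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind in GRID_KINDS:
        write_grid(getattr(bundle, kind), directory / f"{kind}.grid")


def read_bundle(directory) -> GridBundle:
    directory = Path(directory)
    grids = {}
    for kind in GRID_KINDS:
        p = directory / f"{kind}.grid"
        if not p.exists():
            p = directory / f"{kind}.grid.gz"
        grids[kind] = read_grid(p)
    return GridBundle(**grids)
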