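"""Ligand data model and flexibase I/O.

A *flexibase hierarchy* stores one molecule (atoms, bonds, charges, per-atom
desolvation terms) together with an ensemble of pre-built conformers that all
share a fixed *rigid component* — typically the largest ring system.  One
placement of the rigid component therefore positions every conformer at once,
and only complete input conformations are ever docked: conformers are never
recombined from pieces of different inputs, which is what used to create
internally clashing geometries.

Two on-disk representations are supported:

* TRIPOS mol2 (multi-MOLECULE files; consecutive molecules with identical
  atom/bond blocks are grouped into one hierarchy, one conformer each);
* ``db2-lite``, this package's documented hierarchy dialect (see
  ``docs/db2lite.md``), which additionally carries the rigid-component list,
  per-atom desolvation terms and per-conformer builder energies.  Reading is
  gzip-transparent.

The module also implements the two conformer-hygiene operations applied at
build time: resetting hydroxyl protons to low-energy rotamers (in-plane on
sp2 carbons, three equiangular positions on sp3 carbons) and filtering the
ensemble to an energy window above the minimum-energy conformer.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import InputError, ParseError, UndockableMoleculeError
from .vdw import lookup_vdw

__all__ = [
    "Atom",
    "Bond",
    "ConformerHierarchy",
    "EnergyWindow",
    "read_mol2",
    "write_mol2",
    "read_db2lite",
    "write_db2lite",
    "find_rigid_component",
    "reset_hydroxyls",
    "energy_window_filter",
    "dihedral",
]

log = logging.getLogger(__name__)

BOND_ORDERS = ("1", "2", "3", "am", "ar")
RIGID_TOLERANCE = 1e-3  # A; max rigid-component deviation across conformers


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    mol2_type: str
    partial_charge: float = 0.0
    vdw_class: str | None = None
    desolvation_energy: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.partial_charge):
            raise InputError(f"atom {self.index}: non-finite charge")
        if self.vdw_class is None:
            object.__setattr__(self, "vdw_class", self.mol2_type)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def sqrt_ab(self) -> tuple[float, float]:
        return lookup_vdw(self.vdw_class)


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str = "1"

    def __post_init__(self):
        if self.i == self.j:
            raise InputError("bond endpoints must be distinct")
        if self.order not in BOND_ORDERS:
            raise InputError(f"unknown bond order {self.order!r}")


@dataclass(frozen=True)
class EnergyWindow:
    """Width (kcal/mol) of the conformer energy window above the minimum."""

    width: float

    def __post_init__(self):
        if self.width < 0:
            raise InputError("energy window must be >= 0")


def _kabsch_residual(p: np.ndarray, q: np.ndarray) -> float:
    """RMS residual of the optimal proper superposition of p onto q."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    u, _, vt = np.linalg.svd(p0.T @ q0)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return float(np.sqrt(np.mean(np.sum((p0 @ rot.T - q0) ** 2, axis=1))))


@dataclass
class ConformerHierarchy:
    """A molecule with its whole-conformation ensemble and rigid component."""

    name: str
    atoms: list[Atom]
    bonds: list[Bond]
    conformers: list[np.ndarray]
    conformer_energies: list[float] = field(default_factory=list)
    rigid_component: list[int] | None = None

    def __post_init__(self):
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise InputError(f"bond ({b.i},{b.j}) out of range for {n} atoms")
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        for c in self.conformers:
            if c.shape != (n, 3):
                raise InputError(f"conformer block shape {c.shape} != ({n}, 3)")
        if not self.conformer_energies:
            self.conformer_energies = [0.0] * len(self.conformers)
        if len(self.conformer_energies) != len(self.conformers):
            raise InputError("one energy per conformer required")
        if self.rigid_component is None and self.conformers:
            try:
                self.rigid_component = find_rigid_component(self)
            except UndockableMoleculeError as exc:
                log.warning("%s", exc)
                self.rigid_component = []
        if self.rigid_component:
            self.validate_rigid()

    @property
    def dockable(self) -> bool:
        return len(self.rigid_heavy_indices) >= 3

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def rigid_heavy_indices(self) -> list[int]:
        return [i for i in self.rigid_component if self.atoms[i].is_heavy]

    def validate_rigid(self) -> None:
        """Check all conformers share the rigid-component geometry (<= 1 mA)."""
        idx = list(self.rigid_component)
        ref = self.conformers[0][idx]
        for k, conf in enumerate(self.conformers[1:], start=1):
            dev = float(np.abs(conf[idx] - ref).max())
            if dev > RIGID_TOLERANCE and _kabsch_residual(conf[idx], ref) > RIGID_TOLERANCE:
                raise InputError(
                    f"{self.name}: conformer {k} rigid component deviates "
                    f"{dev:.4f} A from conformer 0 (limit {RIGID_TOLERANCE} A)")


# ---------------------------------------------------------------------------
# Rigid-component perception
# ---------------------------------------------------------------------------

def _heavy_graph(mol: ConformerHierarchy) -> nx.Graph:
    g = nx.Graph()
    for a in mol.atoms:
        if a.is_heavy:
            g.add_node(a.index)
    for b in mol.bonds:
        if mol.atoms[b.i].is_heavy and mol.atoms[b.j].is_heavy:
            g.add_edge(b.i, b.j, order=b.order)
    return g


def _is_amide_bond(mol: ConformerHierarchy, i: int, j: int) -> bool:
    """C-N single bond where the carbon also carries a C=O."""
    ai, aj = mol.atoms[i], mol.atoms[j]
    pairs = ((ai, aj), (aj, ai))
    for c, n in pairs:
        if c.element != "C" or n.element != "N":
            continue
        for b in mol.bonds:
            if b.order == "2" and c.index in (b.i, b.j):
                other = b.j if b.i == c.index else b.i
                if mol.atoms[other].element == "O":
                    return True
    return False


def find_rigid_component(mol: ConformerHierarchy) -> list[int]:
    """Heavy atoms of the largest fused ring system (ties: lowest indices).

    Ring bonds are the non-bridge edges of the heavy-atom graph, so ring
    systems joined by a rotatable single bond (e.g. biphenyl) count as
    separate systems.  For acyclic molecules the fallback is the largest set
    of heavy atoms connected exclusively by non-rotatable bonds (terminal,
    amide, double/triple/aromatic).  Fewer than 3 rigid heavy atoms flags the
    molecule undockable.
    """
    if sum(a.is_heavy for a in mol.atoms) < 3:
        raise UndockableMoleculeError(f"{mol.name}: fewer than 3 heavy atoms")
    g = _heavy_graph(mol)
    ring_graph = g.copy()
    ring_graph.remove_edges_from(nx.bridges(g))
    ring_graph.remove_nodes_from([n for n in list(ring_graph) if ring_graph.degree(n) == 0])
    candidates = [sorted(c) for c in nx.connected_components(ring_graph) if len(c) >= 3]
    if candidates:
        return sorted(candidates, key=lambda c: (-len(c), c))[0]

    # acyclic: keep only non-rotatable bonds
    rigid = nx.Graph()
    rigid.add_nodes_from(g.nodes)
    for i, j, data in g.edges(data=True):
        terminal = g.degree(i) == 1 or g.degree(j) == 1
        if data["order"] in ("2", "3", "ar", "am") or terminal or _is_amide_bond(mol, i, j):
            rigid.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(rigid) if len(c) >= 3]
    if not comps:
        raise UndockableMoleculeError(f"{mol.name}: no rigid component of >= 3 heavy atoms")
    return sorted(comps, key=lambda c: (-len(c), c))[0]


# ---------------------------------------------------------------------------
# Hydroxyl rotamer resetting
# ---------------------------------------------------------------------------

def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in radians, in (-pi, pi]."""
    b1 = np.asarray(b) - np.asarray(a)
    b2 = np.asarray(c) - np.asarray(b)
    b3 = np.asarray(d) - np.asarray(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = math.atan2(float(m1 @ n2), float(n1 @ n2))
    return math.pi if abs(ang + math.pi) < 1e-12 else ang


def _rotate_about_axis(point, origin, axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    v = np.asarray(point, float) - origin
    cos, sin = math.cos(angle), math.sin(angle)
    rotated = v * cos + np.cross(axis, v) * sin + axis * (axis @ v) * (1 - cos)
    return origin + rotated


def _set_dihedral(coords, a, b, c, d, target):
    """Return coords with atom d rotated about the b-c axis to the target dihedral."""
    cur = dihedral(coords[a], coords[b], coords[c], coords[d])
    for delta in (target - cur, cur - target):
        new = coords.copy()
        new[d] = _rotate_about_axis(coords[d], coords[c], coords[c] - coords[b], delta)
        if abs(_wrap(dihedral(new[a], new[b], new[c], new[d]) - target)) < 1e-9:
            return new
    raise AssertionError("dihedral rotation failed to converge")  # pragma: no cover


def _wrap(angle: float) -> float:
    return (angle + math.pi) % (2 * math.pi) - math.pi


def _hydroxyls(mol: ConformerHierarchy):
    """Yield (carbon, oxygen, hydrogen, reference substituent, sp2?) tuples."""
    adj: dict[int, list[Bond]] = {a.index: [] for a in mol.atoms}
    for b in mol.bonds:
        adj[b.i].append(b)
        adj[b.j].append(b)
    for o in mol.atoms:
        if o.element != "O":
            continue
        nbrs = [mol.atoms[b.j if b.i == o.index else b.i] for b in adj[o.index]]
        heavies = [n for n in nbrs if n.is_heavy]
        hs = [n for n in nbrs if not n.is_heavy]
        if len(heavies) != 1 or heavies[0].element != "C":
            continue
        if not hs:
            log.warning("%s: hydroxyl oxygen %d has no hydrogen; skipped", mol.name, o.index)
            continue
        carbon = heavies[0]
        c_bonds = adj[carbon.index]
        sp2 = any(b.order in ("2", "ar") for b in c_bonds)
        refs = sorted(
            mol.atoms[b.j if b.i == carbon.index else b.i].index
            for b in c_bonds
            if (b.j if b.i == carbon.index else b.i) != o.index
            and mol.atoms[b.j if b.i == carbon.index else b.i].is_heavy
        )
        if not refs:
            continue
        yield carbon.index, o.index, hs[0].index, refs[0], sp2


def reset_hydroxyls(
    mol: ConformerHierarchy, conformer: np.ndarray, max_combinations: int = 32
) -> list[np.ndarray]:
    """Replace arbitrary hydroxyl proton placements with low-energy rotamers.

    Small-molecule crystal structures show aromatic hydroxyls almost always in
    the ring plane, whereas builders frequently leave them out of plane.  For
    each O-H on an sp2 carbon the two in-plane rotamers (ref-C-O-H dihedral 0
    and pi) are generated; on an sp3 carbon, three staggered rotamers at
    2*pi/3 spacing.  The Cartesian product over independent hydroxyls is
    capped at ``max_combinations``, pruning later-indexed hydroxyls to their
    first rotamer once the cap would be exceeded.
    """
    conformer = np.asarray(conformer, dtype=float)
    groups = list(_hydroxyls(mol))
    if not groups:
        return [conformer.copy()]
    rotamer_sets = []
    product = 1
    for carbon, oxygen, hydrogen, ref, sp2 in groups:
        targets = [0.0, math.pi] if sp2 else [math.pi / 3, math.pi, -math.pi / 3]
        keep = max(1, max_combinations // product)
        targets = targets[:keep]
        product *= len(targets)
        rotamer_sets.append((ref, carbon, oxygen, hydrogen, targets))

    results = [conformer.copy()]
    for ref, carbon, oxygen, hydrogen, targets in rotamer_sets:
        expanded = []
        for coords in results:
            for t in targets:
                expanded.append(_set_dihedral(coords, ref, carbon, oxygen, hydrogen, t))
        results = expanded
    return results


# ---------------------------------------------------------------------------
# Energy-window filtering
# ---------------------------------------------------------------------------

def energy_window_filter(mol: ConformerHierarchy, window: EnergyWindow) -> ConformerHierarchy:
    """Keep conformers within ``window.width`` kcal/mol of the ensemble minimum.

    The minimum-energy conformer is always kept and input order is preserved.
    """
    energies = np.asarray(mol.conformer_energies, dtype=float)
    emin = energies.min()
    keep = [k for k, e in enumerate(energies) if e - emin <= window.width]
    return ConformerHierarchy(
        name=mol.name,
        atoms=mol.atoms,
        bonds=mol.bonds,
        conformers=[mol.conformers[k] for k in keep],
        conformer_energies=[mol.conformer_energies[k] for k in keep],
        rigid_component=list(mol.rigid_component),
    )


# ---------------------------------------------------------------------------
# TRIPOS mol2
# ---------------------------------------------------------------------------

_ELEMENTS = {"H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I", "B", "SI"}


def _element_from_type(mol2_type: str, name: str) -> str:
    prefix = mol2_type.split(".")[0]
    if prefix.upper() in _ELEMENTS:
        return prefix.capitalize() if len(prefix) > 1 else prefix.upper()
    log.warning("unknown mol2 atom type %r; inferring element from name %r", mol2_type, name)
    sym = "".join(ch for ch in name if ch.isalpha())[:2]
    if sym[:2].upper() in _ELEMENTS:
        return sym[:2].capitalize()
    return sym[:1].upper()


def _parse_mol2_blocks(text: str):
    """Split mol2 text into (name, energy, atom lines, bond lines) per MOLECULE."""
    lines = text.splitlines()
    blocks = []
    i = 0
    pending_energy = None
    while i < len(lines):
        line = lines[i]
        if line.startswith("#"):
            if "conformer_energy" in line:
                try:
                    pending_energy = float(line.split()[-1])
                except ValueError:
                    pass
            i += 1
            continue
        if line.strip() == "@<TRIPOS>MOLECULE":
            header = lines[i + 1].strip() if i + 1 < len(lines) else ""
            atoms, bonds = [], []
            section = None
            j = i + 2
            while j < len(lines) and lines[j].strip() != "@<TRIPOS>MOLECULE":
                s = lines[j].strip()
                if s.startswith("@<TRIPOS>"):
                    section = s[9:]
                elif s and not s.startswith("#"):
                    if section == "ATOM":
                        atoms.append((j + 1, s))
                    elif section == "BOND":
                        bonds.append((j + 1, s))
                j += 1
            blocks.append((header, pending_energy, atoms, bonds))
            pending_energy = None
            i = j
        else:
            if line.strip() and not line.startswith("#"):
                raise ParseError(f"unexpected content outside mol2 sections: {line!r}",
                                 line=i + 1)
            i += 1
    if not blocks:
        raise ParseError("no @<TRIPOS>MOLECULE record found")
    return blocks


def read_mol2(source) -> list[ConformerHierarchy]:
    """Read a (multi-)MOLECULE TRIPOS mol2 file into hierarchies.

    Consecutive molecules with identical atom/bond blocks (names, types,
    charges, bonds) are grouped into a single hierarchy with one conformer
    per MOLECULE record.
    """
    text = _read_text(source)
    molecules = []
    for header, energy, atom_lines, bond_lines in _parse_mol2_blocks(text):
        atoms, coords = [], []
        for lineno, s in atom_lines:
            parts = s.split()
            if len(parts) < 6:
                raise ParseError(f"malformed ATOM record: {s!r}", line=lineno)
            name, x, y, z, mol2_type = parts[1], *map(float, parts[2:5]), parts[5]
            charge = float(parts[8]) if len(parts) > 8 else 0.0
            atoms.append(Atom(
                index=len(atoms), name=name,
                element=_element_from_type(mol2_type, name),
                mol2_type=mol2_type, partial_charge=charge,
            ))
            coords.append([x, y, z])
        bonds = []
        for lineno, s in bond_lines:
            parts = s.split()
            if len(parts) < 4:
                raise ParseError(f"malformed BOND record: {s!r}", line=lineno)
            bonds.append(Bond(int(parts[1]) - 1, int(parts[2]) - 1, parts[3]))
        molecules.append((header, energy, atoms, bonds, np.array(coords)))

    hierarchies: list[ConformerHierarchy] = []
    for header, energy, atoms, bonds, coords in molecules:
        prev = hierarchies[-1] if hierarchies else None
        if prev is not None and prev.name == header and _same_topology(prev, atoms, bonds):
            prev.conformers.append(coords)
            prev.conformer_energies.append(energy if energy is not None else 0.0)
            if prev.rigid_component:
                prev.validate_rigid()
        else:
            hierarchies.append(ConformerHierarchy(
                name=header, atoms=atoms, bonds=bonds,
                conformers=[coords],
                conformer_energies=[energy if energy is not None else 0.0],
            ))
    return hierarchies


def _same_topology(h: ConformerHierarchy, atoms, bonds) -> bool:
    if len(h.atoms) != len(atoms) or len(h.bonds) != len(bonds):
        return False
    for a, b in zip(h.atoms, atoms):
        if (a.name, a.mol2_type, round(a.partial_charge, 4)) != \
           (b.name, b.mol2_type, round(b.partial_charge, 4)):
            return False
    return all((x.i, x.j, x.order) == (y.i, y.j, y.order) for x, y in zip(h.bonds, bonds))


def write_mol2(mol: ConformerHierarchy, stream=None, comments: list[list[str]] | None = None) -> str:
    """Write every conformer as a MOLECULE block; returns the text.

    ``comments`` optionally supplies extra ``#`` comment lines per conformer
    (used by the engine to attach score breakdowns to poses).
    """
    out = io.StringIO()
    for k, coords in enumerate(mol.conformers):
        if comments and k < len(comments):
            for c in comments[k]:
                out.write(f"# {c}\n")
        out.write(f"# conformer_energy {mol.conformer_energies[k]:.6f}\n")
        out.write("@<TRIPOS>MOLECULE\n")
        out.write(f"{mol.name}\n")
        out.write(f"{mol.n_atoms} {len(mol.bonds)} 0 0 0\n")
        out.write("SMALL\nUSER_CHARGES\n")
        out.write("@<TRIPOS>ATOM\n")
        for a, (x, y, z) in zip(mol.atoms, coords):
            out.write(f"{a.index + 1:>4} {a.name:<4} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                      f"{a.mol2_type:<6} 1 LIG {a.partial_charge:>8.4f}\n")
        out.write("@<TRIPOS>BOND\n")
        for n, b in enumerate(mol.bonds, start=1):
            out.write(f"{n:>4} {b.i + 1:>4} {b.j + 1:>4} {b.order}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# db2-lite
# ---------------------------------------------------------------------------

def write_db2lite(mol: ConformerHierarchy, target=None) -> str:
    """Serialise a hierarchy to the db2-lite text dialect (docs/db2lite.md)."""
    out = io.StringIO()
    out.write("db2lite 1\n")
    out.write(f"name {mol.name}\n")
    out.write(f"counts {mol.n_atoms} {len(mol.bonds)} {mol.n_conformers}\n")
    for a in mol.atoms:
        out.write(f"atom {a.index} {a.name} {a.element} {a.mol2_type} "
                  f"{a.partial_charge:.6f} {a.vdw_class} {a.desolvation_energy:.6f}\n")
    for b in mol.bonds:
        out.write(f"bond {b.i} {b.j} {b.order}\n")
    out.write("rigid " + " ".join(str(i) for i in mol.rigid_component) + "\n")
    for k, coords in enumerate(mol.conformers):
        out.write(f"conf {k} {mol.conformer_energies[k]:.6f}\n")
        for x, y, z in coords:
            out.write(f"coord {x:.6f} {y:.6f} {z:.6f}\n")
    out.write("end\n")
    text = out.getvalue()
    if target is None:
        return text
    if isinstance(target, (str, Path)):
        path = Path(target)
        if path.suffix == ".gz":
            with gzip.open(path, "wt") as fh:
                fh.write(text)
        else:
            path.write_text(text)
    else:
        target.write(text)
    return text


def _read_text(source) -> str:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        if path.exists():
            if path.suffix == ".gz":
                with gzip.open(path, "rt") as fh:
                    return fh.read()
            return path.read_text()
    if isinstance(source, bytes):
        if source[:2] == b"\x1f\x8b":
            return gzip.decompress(source).decode()
        return source.decode()
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            return data.decode()
        return data
    return str(source)


def read_db2lite(source) -> list[ConformerHierarchy]:
    """Read one or more db2-lite records; accepts path, text or stream (gzip ok)."""
    text = _read_text(source)
    lines = text.splitlines()
    records: list[ConformerHierarchy] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("db2lite"):
            raise ParseError(f"expected 'db2lite' header, got {line!r}", line=i + 1)
        i += 1
        name, counts = None, None
        atoms, bonds, rigid = [], [], None
        conformers, energies = [], []
        current_coords = None
        while i < len(lines):
            parts = lines[i].split()
            i += 1
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "end":
                break
            if tag == "name":
                name = " ".join(parts[1:])
            elif tag == "counts":
                counts = tuple(int(x) for x in parts[1:4])
            elif tag == "atom":
                atoms.append(Atom(int(parts[1]), parts[2], parts[3], parts[4],
                                  float(parts[5]), parts[6], float(parts[7])))
            elif tag == "bond":
                bonds.append(Bond(int(parts[1]), int(parts[2]), parts[3]))
            elif tag == "rigid":
                rigid = [int(x) for x in parts[1:]]
            elif tag == "conf":
                current_coords = []
                conformers.append(current_coords)
                energies.append(float(parts[2]))
            elif tag == "coord":
                if current_coords is None:
                    raise ParseError("coord before conf", line=i)
                current_coords.append([float(x) for x in parts[1:4]])
            else:
                raise ParseError(f"unknown db2-lite tag {tag!r}", line=i)
        if name is None or counts is None or rigid is None:
            raise ParseError("incomplete db2-lite record (need name/counts/rigid)")
        if counts != (len(atoms), len(bonds), len(conformers)):
            raise ParseError(
                f"counts {counts} disagree with parsed "
                f"({len(atoms)}, {len(bonds)}, {len(conformers)})")
        records.append(ConformerHierarchy(
            name=name, atoms=atoms, bonds=bonds,
            conformers=[np.array(c) for c in conformers],
            conformer_energies=energies, rigid_component=rigid,
        ))
    if not records:
        raise ParseError("no db2-lite records found")
    return records
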