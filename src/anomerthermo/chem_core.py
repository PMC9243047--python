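"""Molecular geometry, torsions, bond perception and XYZ/Z-matrix I/O.

A :class:`Geometry` is an ordered list of atoms (element symbol + Cartesian
coordinates in Å) with a net charge and optional per-atom labels such as
``C5'`` or ``O4'``. Bonds are perceived from covalent radii; torsions are
measured and driven with the IUPAC sign convention, range (−180°, +180°].
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from collections import Counter

import numpy as np

from .constants import ATOMIC_MASSES, BOND_TOLERANCE_FACTOR, COVALENT_RADII
from .errors import DegenerateTorsionError, ParseError, RingTorsionError

__all__ = [
    "Geometry",
    "DihedralSpec",
    "BondGraph",
    "bond_graph",
    "measure_dihedral",
    "set_dihedral",
    "molecular_formula",
    "read_xyz",
    "write_xyz",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_zmatrix",
    "place_atom",
]


@dataclass(frozen=True)
class Geometry:
    """An ordered molecular geometry in Å.

    Atom order is significant: dihedral specs, bond graphs and conformer
    records all reference atoms by 0-based index into this order, and the
    order is stable under XYZ read/write round trips.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3) float64, Å
    charge: int = 0
    label: str = ""
    atom_labels: tuple[str, ...] | None = None  # e.g. ("C1'", "O4'", ...)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) != len(coords):
            raise ValueError(
                f"{len(self.elements)} element symbols but {len(coords)} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        unknown = [e for e in self.elements if e not in COVALENT_RADII]
        if unknown:
            raise ValueError(f"unknown element symbols: {sorted(set(unknown))}")
        if self.atom_labels is not None:
            labels = tuple(self.atom_labels)
            if len(labels) != len(self.elements):
                raise ValueError("atom_labels length mismatch")
            object.__setattr__(self, "atom_labels", labels)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def masses(self) -> np.ndarray:
        """Atomic masses in amu, in atom order."""
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def index_of_label(self, name: str) -> int:
        """0-based index of the atom labelled *name*; KeyError if absent."""
        if self.atom_labels is None:
            raise KeyError(f"geometry '{self.label}' carries no atom labels")
        try:
            return self.atom_labels.index(name)
        except ValueError:
            raise KeyError(f"no atom labelled {name!r} in geometry '{self.label}'")

    def isclose(self, other: "Geometry", tol: float = 1e-6) -> bool:
        return (
            self.elements == other.elements
            and self.coords.shape == other.coords.shape
            and bool(np.all(np.abs(self.coords - other.coords) <= tol))
        )


@dataclass(frozen=True)
class DihedralSpec:
    """Four 0-based atom indices i-j-k-l defining a torsion, plus a label."""

    i: int
    j: int
    k: int
    l: int
    label: str = ""

    @property
    def indices(self) -> tuple[int, int, int, int]:
        return (self.i, self.j, self.k, self.l)

    def validate(self, geom: Geometry, graph: "BondGraph | None" = None) -> None:
        idx = self.indices
        if len(set(idx)) != 4:
            raise IndexError(f"dihedral indices must be pairwise distinct: {idx}")
        for a in idx:
            if not (0 <= a < geom.n_atoms):
                raise IndexError(f"atom index {a} out of range for {geom.n_atoms} atoms")
        if graph is not None:
            for a, b in zip(idx[:-1], idx[1:]):
                if b not in graph.neighbors(a):
                    raise ValueError(
                        f"consecutive dihedral atoms {a}-{b} are not bonded"
                    )


class BondGraph:
    """Symmetric covalent-bond adjacency over atom indices.

    Bonds are perceived where the interatomic distance does not exceed the
    sum of covalent radii times a fixed tolerance factor. Deterministic for
    a fixed geometry.
    """

    def __init__(self, n_atoms: int, edges: set[frozenset[int]]):
        self.n_atoms = n_atoms
        self.edges = frozenset(edges)
        adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
        for e in edges:
            a, b = sorted(e)
            adj[a].add(b)
            adj[b].add(a)
        self._adj = adj

    def neighbors(self, i: int) -> frozenset[int]:
        return frozenset(self._adj[i])

    def has_bond(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.edges

    def components_without(self, i: int, j: int) -> list[set[int]]:
        """Connected components after removing the i-j edge (order: by min index)."""
        removed = frozenset((i, j))
        seen: set[int] = set()
        comps = []
        for start in range(self.n_atoms):
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                a = stack.pop()
                if a in comp:
                    continue
                comp.add(a)
                for b in self._adj[a]:
                    if frozenset((a, b)) == removed:
                        continue
                    if b not in comp:
                        stack.append(b)
            seen |= comp
            comps.append(comp)
        return comps


def bond_graph(geom: Geometry, tolerance_factor: float = BOND_TOLERANCE_FACTOR) -> BondGraph:
    """Perceive covalent bonds from distances and covalent radii."""
    coords = geom.coords
    radii = np.array([COVALENT_RADII[e] for e in geom.elements])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cutoff = (radii[:, None] + radii[None, :]) * tolerance_factor
    edges = set()
    n = geom.n_atoms
    for a in range(n):
        for b in range(a + 1, n):
            if dist[a, b] <= cutoff[a, b]:
                edges.add(frozenset((a, b)))
    return BondGraph(n, edges)


def _torsion_from_points(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or b2n < 1e-10:
        raise DegenerateTorsionError(
            "collinear atoms: torsion angle undefined"
        )
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def measure_dihedral(geom: Geometry, spec: DihedralSpec) -> float:
    """Signed IUPAC torsion angle i-j-k-l in degrees, range (−180, +180]."""
    spec.validate(geom)
    c = geom.coords
    return _torsion_from_points(c[spec.i], c[spec.j], c[spec.k], c[spec.l])


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * K + (1.0 - c) * np.outer(axis, axis)


def set_dihedral(
    geom: Geometry,
    spec: DihedralSpec,
    target_deg: float,
    graph: BondGraph | None = None,
) -> Geometry:
    """Return a geometry with torsion *spec* driven to *target_deg*.

    The central j-k bond must split the bond graph into exactly two
    components (i.e. not lie in a ring); the component containing k (the
    "distal" side) is rotated rigidly about the j→k axis, the anchor side
    is left untouched.
    """
    spec.validate(geom)
    if graph is None:
        graph = bond_graph(geom)
    comps = graph.components_without(spec.j, spec.k)
    if len(comps) != 2:
        raise RingTorsionError(
            f"central bond {spec.j}-{spec.k} does not split the molecule in two "
            f"(got {len(comps)} components): ring torsion or disconnected geometry"
        )
    moving = next(c for c in comps if spec.k in c)
    if spec.j in moving:
        raise RingTorsionError(
            f"central bond {spec.j}-{spec.k} lies inside a ring"
        )
    current = measure_dihedral(geom, spec)
    delta = target_deg - current
    axis = geom.coords[spec.k] - geom.coords[spec.j]
    idx = sorted(moving)
    origin = geom.coords[spec.j]

    def rotated(angle: float) -> Geometry:
        R = _rotation_matrix(axis, angle)
        coords = geom.coords.copy()
        coords[idx] = (coords[idx] - origin) @ R.T + origin
        return geom.with_coords(coords)

    # rotating the k-side by +δ about the j→k axis advances the torsion by +δ;
    # verify and flip defensively so the contract never depends on handedness.
    out = rotated(delta)
    err = abs(_wrap_deg(measure_dihedral(out, spec) - target_deg))
    if err > 1e-9:
        alt = rotated(-delta)
        if abs(_wrap_deg(measure_dihedral(alt, spec) - target_deg)) < err:
            out = alt
    return out


def _wrap_deg(angle: float) -> float:
    """Wrap an angle difference into (−180, +180]."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def molecular_formula(geom: Geometry) -> str:
    """Hill-notation molecular formula ("" for an empty geometry)."""
    counts = Counter(geom.elements)
    if not counts:
        return ""
    parts = []
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else []) + sorted(
            e for e in counts if e not in ("C", "H")
        )
    else:
        order = sorted(counts)
    for e in order:
        n = counts[e]
        parts.append(e + (str(n) if n > 1 else ""))
    return "".join(parts)


# --------------------------------------------------------------------------
# XYZ I/O (standard dialect: count line, comment line, element + 3 floats)
# --------------------------------------------------------------------------

def write_xyz(geom: Geometry, comment: str | None = None) -> str:
    comment = geom.label if comment is None else comment
    lines = [str(geom.n_atoms), comment.replace("\n", " ")]
    for e, (x, y, z) in zip(geom.elements, geom.coords):
        lines.append(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    return "\n".join(lines) + "\n"


def _parse_xyz_block(lines: list[str], offset: int) -> Geometry:
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("expected an atom count", line=offset + 1)
    if n < 0:
        raise ParseError("negative atom count", line=offset + 1)
    if len(lines) < n + 2:
        raise ParseError(
            f"count line declares {n} atoms but only {len(lines) - 2} rows follow",
            line=offset + 1,
        )
    comment = lines[1].strip() if len(lines) > 1 else ""
    elements, coords = [], []
    for r, raw in enumerate(lines[2 : 2 + n]):
        parts = raw.split()
        if len(parts) < 4:
            raise ParseError(f"malformed atom row: {raw!r}", line=offset + 3 + r)
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"non-numeric coordinate in row: {raw!r}", line=offset + 3 + r)
        elements.append(parts[0])
        coords.append(xyz)
    return Geometry(tuple(elements), np.array(coords).reshape(-1, 3), label=comment)


def _xyz_lines(text: str) -> list[str]:
    lines = text.splitlines()
    while lines and lines[-1].strip() == "":
        lines.pop()
    return lines


def read_xyz(text: str) -> Geometry:
    lines = _xyz_lines(text)
    if not lines:
        raise ParseError("empty XYZ text", line=1)
    geom = _parse_xyz_block(lines, 0)
    declared = int(lines[0].split()[0])
    if len(lines) > declared + 2:
        raise ParseError(
            f"count line declares {declared} atoms but {len(lines) - 2} rows present",
            line=1,
        )
    return geom


def read_xyz_frames(text: str) -> list[Geometry]:
    """Read a concatenated multi-record XYZ file."""
    lines = _xyz_lines(text)
    frames, pos = [], 0
    while pos < len(lines):
        try:
            n = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise ParseError("expected an atom count", line=pos + 1)
        frames.append(_parse_xyz_block(lines[pos : pos + n + 2], pos))
        pos += n + 2
    return frames


def write_xyz_frames(geoms: list[Geometry]) -> str:
    return "".join(write_xyz(g) for g in geoms)


# --------------------------------------------------------------------------
# Z-matrix reading (element, refs, bond length Å, angle °, dihedral °)
# --------------------------------------------------------------------------

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, angle_deg: float, dihedral_deg: float
) -> np.ndarray:
    """Position a new atom X at distance *r* from *a*, angle X-a-b, torsion X-a-b-c.

    Standard internal-coordinate (NeRF) construction.
    """
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    u = b - a
    un = np.linalg.norm(u)
    if un < 1e-10:
        raise DegenerateTorsionError("coincident reference atoms for placement")
    u = u / un
    cb = c - b
    p = cb - np.dot(cb, u) * u
    pn = np.linalg.norm(p)
    if pn < 1e-10:
        raise DegenerateTorsionError("reference atoms for placement are collinear")
    v = p / pn
    w = np.cross(u, v)
    # X = a + r(cosθ·u + sinθ(cosφ·v − sinφ·w)) gives torsion X-a-b-c = φ
    # under the IUPAC sign convention of measure_dihedral.
    return a + r * (
        math.cos(theta) * u
        + math.sin(theta) * (math.cos(phi) * v - math.sin(phi) * w)
    )


_ZLINE = re.compile(r"^\s*([A-Z][a-z]?)\b")


def read_zmatrix(text: str, charge: int = 0, label: str = "") -> Geometry:
    """Build Cartesian coordinates from a plain-text Z-matrix.

    Row formats (1-based references, lengths in Å, angles/torsions in °)::

        El
        El  r1 dist
        El  r1 dist  r2 angle
        El  r1 dist  r2 angle  r3 dihedral
    """
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")]
    elements: list[str] = []
    coords: list[np.ndarray] = []
    for lineno, raw in enumerate(rows, start=1):
        parts = raw.split()
        if not _ZLINE.match(raw):
            raise ParseError(f"expected an element symbol: {raw!r}", line=lineno)
        el = parts[0]
        i = len(coords)
        try:
            if i == 0:
                if len(parts) != 1:
                    raise ParseError("first row takes no references", line=lineno)
                pos = np.zeros(3)
            elif i == 1:
                r1, dist = int(parts[1]), float(parts[2])
                _check_ref(r1, i, lineno)
                pos = coords[r1 - 1] + np.array([dist, 0.0, 0.0])
            elif i == 2:
                r1, dist, r2, ang = int(parts[1]), float(parts[2]), int(parts[3]), float(parts[4])
                _check_ref(r1, i, lineno), _check_ref(r2, i, lineno)
                a, b = coords[r1 - 1], coords[r2 - 1]
                ab = b - a
                ab_hat = ab / np.linalg.norm(ab)
                # in-plane placement in the xy plane
                perp = np.array([-ab_hat[1], ab_hat[0], 0.0])
                if np.linalg.norm(perp) < 1e-10:
                    perp = np.array([1.0, 0.0, 0.0])
                perp = perp / np.linalg.norm(perp)
                t = math.radians(ang)
                # angle X-a-b: component of a→X along a→b is cos(t)
                pos = a + dist * (math.cos(t) * ab_hat + math.sin(t) * perp)
            else:
                r1, dist, r2, ang, r3, dih = (
                    int(parts[1]),
                    float(parts[2]),
                    int(parts[3]),
                    float(parts[4]),
                    int(parts[5]),
                    float(parts[6]),
                )
                for rr in (r1, r2, r3):
                    _check_ref(rr, i, lineno)
                pos = place_atom(
                    coords[r1 - 1], coords[r2 - 1], coords[r3 - 1], dist, ang, dih
                )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed Z-matrix row {raw!r} ({exc})", line=lineno)
        elements.append(el)
        coords.append(np.asarray(pos, dtype=float))
    if not elements:
        raise ParseError("empty Z-matrix", line=1)
    return Geometry(tuple(elements), np.array(coords), charge=charge, label=label)


def _check_ref(ref: int, current: int, lineno: int) -> None:
    if not (1 <= ref <= current):
        raise ParseError(f"reference {ref} out of range", line=lineno)


def rigid_transform(
    geom: Geometry, rotation: np.ndarray | None = None, translation: np.ndarray | None = None
) -> Geometry:
    """Apply a global rigid motion (used in invariance tests and preprocessing)."""
    coords = geom.coords
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    if translation is not None:
        coords = coords + np.asarray(translation)
    return geom.with_coords(coords)
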