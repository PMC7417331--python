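"""Mesh construction and geometric queries.

The admittance method discretizes a conductive tissue volume into either a
structured cubic-voxel (hexahedral) grid or an unstructured tetrahedral mesh.
This module builds both kinds of mesh, answers the geometric queries the rest
of the pipeline needs (point location, nearest node, dihedral angles), and
reads/writes the two external ASCII mesh dialects (Gmsh MSH, TetGen).

All coordinates are micrometres.  Node and element indices are 0-based
internally; 1-based external formats are normalized on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "BoundingBox",
    "HexMesh",
    "TetMesh",
    "MeshStats",
    "MeshError",
    "OutsideMeshError",
    "scaled_bounding_box",
    "build_hex_mesh",
    "generate_tet_mesh",
    "kuhn_tetrahedralize",
    "read_mesh",
    "write_mesh",
    "locate_hex_voxel",
    "locate_tet",
    "nearest_node",
    "dihedral_angle",
    "mesh_stats",
]

#: Default bounding-volume expansion factor: each side of the source cloud's
#: axis-aligned bounding box is stretched by 42% about the box centroid so
#: that fields of edge-most sources are largely relaxed before reaching the
#: grounded hull.
DEFAULT_SCALE_FACTOR = 1.42


class MeshError(ValueError):
    """Invalid mesh, degenerate geometry, or malformed mesh file."""


class OutsideMeshError(MeshError):
    """A query point lies outside the mesh hull (never silently dropped)."""


# ---------------------------------------------------------------------------
# bounding box
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in μm, optionally recording the expansion applied."""

    min_corner: np.ndarray
    max_corner: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "min_corner", np.asarray(self.min_corner, float))
        object.__setattr__(self, "max_corner", np.asarray(self.max_corner, float))
        if not (np.all(np.isfinite(self.min_corner)) and np.all(np.isfinite(self.max_corner))):
            raise MeshError("bounding box corners must be finite")
        if not np.all(self.max_corner > self.min_corner):
            raise MeshError("max_corner must exceed min_corner on every axis")
        if self.scale_factor < 1.0:
            raise MeshError("scale_factor must be >= 1")

    @property
    def sides(self) -> np.ndarray:
        return self.max_corner - self.min_corner

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.min_corner + self.max_corner)

    @property
    def volume(self) -> float:
        return float(np.prod(self.sides))

    def contains(self, points, tol: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        return np.all((p >= self.min_corner - tol) & (p <= self.max_corner + tol), axis=1)


def scaled_bounding_box(points, scale_factor: float = DEFAULT_SCALE_FACTOR) -> BoundingBox:
    """Axis-aligned bounding box of ``points`` expanded about its centroid.

    Each side length is multiplied by ``scale_factor`` (1.42 by default),
    keeping the centroid fixed, so that sources near the cloud edge sit well
    inside the meshed volume.

    Raises
    ------
    MeshError
        If fewer than 2 points are given or the cloud has zero extent along
        any axis (the degenerate axes are named in the message).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise MeshError("points must be an (n, 3) array")
    if len(pts) < 2:
        raise MeshError("need at least 2 points to bound")
    if not np.all(np.isfinite(pts)):
        raise MeshError("points must be finite")
    if scale_factor < 1.0:
        raise MeshError("scale_factor must be >= 1")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    degenerate = np.nonzero(hi - lo <= 0)[0]
    if degenerate.size:
        names = ", ".join("xyz"[a] for a in degenerate)
        raise MeshError(f"point cloud has zero extent along axis {names}")
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo) * scale_factor
    return BoundingBox(center - half, center + half, scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# hexahedral (structured cubic) meshes
# ---------------------------------------------------------------------------

@dataclass
class HexMesh:
    """Structured grid of cubical voxels.

    Nodes form an ``nx × ny × nz`` lattice with spacing ``edge_length``;
    node ``(ix, iy, iz)`` has flat index ``ix + nx*(iy + ny*iz)``.
    """

    origin: np.ndarray
    edge_length: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        if self.edge_length <= 0:
            raise MeshError("edge_length must be positive")
        if any(d < 2 for d in self.dims):
            raise MeshError("need at least 2 nodes per axis")
        self.dims = tuple(int(d) for d in self.dims)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def n_elements(self) -> int:
        nx, ny, nz = self.dims
        return (nx - 1) * (ny - 1) * (nz - 1)

    def node_index(self, ix, iy, iz):
        nx, ny, _ = self.dims
        return ix + nx * (iy + ny * iz)

    def node_positions(self) -> np.ndarray:
        nx, ny, nz = self.dims
        iz, iy, ix = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
        ijk = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        return self.origin + ijk * self.edge_length

    @property
    def max_corner(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 1) * self.edge_length

    def edges(self) -> np.ndarray:
        """All axis-aligned lattice edges as an (n_edges, 2) index array."""
        nx, ny, nz = self.dims
        idx = np.arange(self.n_nodes).reshape(nz, ny, nx)  # [iz, iy, ix]
        pairs = []
        pairs.append(np.stack([idx[:, :, :-1].ravel(), idx[:, :, 1:].ravel()], axis=1))
        pairs.append(np.stack([idx[:, :-1, :].ravel(), idx[:, 1:, :].ravel()], axis=1))
        pairs.append(np.stack([idx[:-1, :, :].ravel(), idx[1:, :, :].ravel()], axis=1))
        return np.concatenate(pairs, axis=0)

    def hull_nodes(self) -> np.ndarray:
        """Indices of lattice-boundary nodes."""
        nx, ny, nz = self.dims
        iz, iy, ix = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
        on_hull = (
            (ix == 0) | (ix == nx - 1) | (iy == 0) | (iy == ny - 1) | (iz == 0) | (iz == nz - 1)
        )
        return np.nonzero(on_hull.ravel())[0]


def build_hex_mesh(box: BoundingBox, edge_length: float) -> HexMesh:
    """Cover ``box`` with a lattice of cubical voxels of side ``edge_length``.

    The lattice is extended outward (centered on the box) whenever the box
    sides are not integer multiples of the edge length, so the box is always
    fully contained; it is never shrunk.
    """
    if edge_length <= 0:
        raise MeshError("edge_length must be positive")
    if edge_length > np.min(box.sides):
        raise MeshError(
            f"edge_length {edge_length} exceeds smallest box side {np.min(box.sides)}"
        )
    n_vox = np.ceil(box.sides / edge_length - 1e-12).astype(int)
    extent = n_vox * edge_length
    origin = box.center - extent / 2.0
    return HexMesh(origin=origin, edge_length=float(edge_length), dims=tuple(n_vox + 1))


# ---------------------------------------------------------------------------
# tetrahedral meshes
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Unstructured tetrahedral mesh: (n, 3) node array + (m, 4) connectivity.

    Tets are stored with positive signed volume (vertices reordered on
    construction if needed).  A KD-tree over tet centroids is built lazily
    for point location.
    """

    nodes: np.ndarray
    tets: np.ndarray
    _centroid_tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _node_tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.tets = np.asarray(self.tets, np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be (m, 4)")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise MeshError("tet connectivity references nodes out of range")
        vols = self.signed_volumes()
        if np.any(vols == 0):
            bad = np.nonzero(vols == 0)[0]
            raise MeshError(f"degenerate (zero-volume) tets: {bad[:10].tolist()}")
        # enforce positive orientation
        neg = vols < 0
        if np.any(neg):
            self.tets = self.tets.copy()
            self.tets[neg, 1], self.tets[neg, 2] = (
                self.tets[neg, 2].copy(),
                self.tets[neg, 1].copy(),
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def node_positions(self) -> np.ndarray:
        return self.nodes

    def signed_volumes(self) -> np.ndarray:
        v = self.nodes[self.tets]
        a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    _EDGE_LOCAL = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (n_edges, 2), each pair sorted."""
        e = np.concatenate([self.tets[:, pair] for pair in self._EDGE_LOCAL], axis=0)
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def boundary_faces(self) -> np.ndarray:
        """Faces that belong to exactly one tet (the mesh hull)."""
        faces = np.concatenate(
            [self.tets[:, idx] for idx in ((1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2))],
            axis=0,
        )
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def hull_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces())

    def centroid_tree(self) -> cKDTree:
        if self._centroid_tree is None:
            self._centroid_tree = cKDTree(self.nodes[self.tets].mean(axis=1))
        return self._centroid_tree

    def node_tree(self) -> cKDTree:
        if self._node_tree is None:
            self._node_tree = cKDTree(self.nodes)
        return self._node_tree


def generate_tet_mesh(box: BoundingBox, max_edge_length: float, seed: int = 0,
                      jitter: float = 0.05) -> TetMesh:
    """Delaunay tetrahedralization of ``box`` with edges ≤ ``max_edge_length``.

    Points are placed on a body-centered-cubic lattice covering the box,
    whose Delaunay triangulation is the tetragonal-disphenoid honeycomb —
    near-equifacial tets with 60°/90° dihedral angles and no obtuse
    elements — plus right-angle tets closing the hull.  A small random
    jitter (interior points on all axes; boundary points only within their
    face, so the hull stays flat) breaks the lattice's cospherical
    degeneracies before triangulation.  The lattice pitch is chosen so that
    even jittered edges respect the requested maximum edge length.
    Deterministic for a fixed seed.

    Parameters
    ----------
    jitter : float
        Perturbation amplitude as a fraction of the lattice pitch, uniform
        in ``[-jitter, +jitter]`` per axis.
    """
    if max_edge_length <= 0:
        raise MeshError("max_edge_length must be positive")
    rng = np.random.default_rng(seed)
    # longest lattice edge is a hull-face diagonal, pitch*sqrt(2), plus jitter
    pitch = max_edge_length / (np.sqrt(2.0) * (1.0 + 2.0 * jitter))
    n_vox = np.maximum(np.ceil(box.sides / pitch - 1e-12).astype(int), 1)
    extent = n_vox * pitch
    origin = box.center - extent / 2.0

    axes = [origin[a] + pitch * np.arange(n_vox[a] + 1) for a in range(3)]
    zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    corners = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    cell_axes = [origin[a] + pitch * (np.arange(n_vox[a]) + 0.5) for a in range(3)]
    zz, yy, xx = np.meshgrid(cell_axes[2], cell_axes[1], cell_axes[0], indexing="ij")
    centers = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    pts = np.concatenate([corners, centers])

    lo, hi = origin, origin + extent
    disp = rng.uniform(-jitter * pitch, jitter * pitch, size=pts.shape)
    on_lo = np.isclose(pts, lo, atol=1e-9 * pitch)
    on_hi = np.isclose(pts, hi, atol=1e-9 * pitch)
    disp[on_lo | on_hi] = 0.0  # keep each boundary plane flat
    pts = pts + disp

    try:
        tri = Delaunay(pts)
    except Exception as exc:  # pragma: no cover - qhull failure path
        raise MeshError(f"Delaunay tetrahedralization failed: {exc}") from exc
    # degenerate hull configurations (coplanar boundary squares) can emit
    # zero-volume simplices; they carry no conductance and are discarded
    v = pts[tri.simplices]
    vol = np.einsum("ij,ij->i", v[:, 1] - v[:, 0],
                    np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])) / 6.0
    keep = np.abs(vol) > 1e-12 * pitch ** 3
    mesh = TetMesh(nodes=pts, tets=tri.simplices[keep])

    edge = mesh.edges()
    elen = np.linalg.norm(mesh.nodes[edge[:, 0]] - mesh.nodes[edge[:, 1]], axis=1)
    if elen.max() > max_edge_length * (1 + 1e-9):
        raise MeshError(
            f"mesher produced edge of length {elen.max():.3f} > {max_edge_length}"
        )
    return mesh


#: Kuhn subdivision: the six tri-rectangular tets of a unit cube sharing the
#: main diagonal (0,0,0)-(1,1,1), expressed as corner-bit indices dx+2dy+4dz.
_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ]
)


def kuhn_tetrahedralize(hex_mesh: HexMesh) -> TetMesh:
    """Split every voxel of a hex mesh into 6 tri-rectangular (Kuhn) tets.

    All voxels share the same main-diagonal orientation, so the result is a
    conforming tetrahedralization of the grid with identical node numbering.
    """
    nx, ny, nz = hex_mesh.dims
    ix, iy, iz = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    base = hex_mesh.node_index(ix.ravel(), iy.ravel(), iz.ravel())
    offs = np.array(
        [hex_mesh.node_index(dx, dy, dz) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
    )
    # corner-bit k = dx + 2dy + 4dz maps to flat offset offs[perm]
    corner_off = np.empty(8, np.int64)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                corner_off[dx + 2 * dy + 4 * dz] = hex_mesh.node_index(dx, dy, dz)
    corners = base[:, None] + corner_off[None, :]  # (n_vox, 8)
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)
    return TetMesh(nodes=hex_mesh.node_positions(), tets=tets)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshStats:
    n_nodes: int
    n_elements: int

    @property
    def elements_per_node(self) -> float:
        return self.n_elements / self.n_nodes


def mesh_stats(mesh) -> MeshStats:
    """Node/element counts and their ratio, for complexity comparisons."""
    return MeshStats(n_nodes=mesh.n_nodes, n_elements=mesh.n_elements)


# ---------------------------------------------------------------------------
# point location
# ---------------------------------------------------------------------------

def locate_hex_voxel(mesh: HexMesh, p, tol: float = 1e-9):
    """Find the voxel containing ``p``.

    Returns ``(corner_indices, local)`` where ``corner_indices`` are the 8
    voxel corner node indices ordered by corner bits (dx + 2dy + 4dz) and
    ``local`` are p's offsets from the voxel min-corner divided by the edge
    length, each in [0, 1].

    Voxels tile the grid with half-open intervals [min, max) per axis (the
    last voxel is closed on top), so every point maps to exactly one voxel:
    a point exactly on a lattice plane belongs to the voxel having it on its
    min face (local coordinate 0), and a point on a lattice node maps to the
    voxel with that node as min corner.
    """
    p = np.asarray(p, float)
    L = mesh.edge_length
    rel = (p - mesh.origin) / L
    n_vox = np.array(mesh.dims) - 1
    if np.any(rel < -tol) or np.any(rel > n_vox + tol):
        raise OutsideMeshError(f"point {p.tolist()} outside mesh hull")
    ijk = np.clip(np.floor(rel + tol).astype(int), 0, n_vox - 1)
    local = np.clip(rel - ijk, 0.0, 1.0)
    off = [mesh.node_index(dx, dy, dz) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
    base = mesh.node_index(*ijk)
    return base + np.asarray(off), local


def barycentric_coordinates(verts, p) -> np.ndarray:
    """Barycentric coordinates of ``p`` in the tet given by (4, 3) ``verts``."""
    verts = np.asarray(verts, float)
    T = (verts[1:] - verts[0]).T
    try:
        lam = np.linalg.solve(T, np.asarray(p, float) - verts[0])
    except np.linalg.LinAlgError as exc:
        raise MeshError("degenerate tetrahedron") from exc
    return np.concatenate([[1.0 - lam.sum()], lam])


def locate_tet(mesh: TetMesh, p, tol: float = 1e-9):
    """Find a tet containing ``p`` and its barycentric coordinates.

    A KD-tree over tet centroids proposes candidates nearest-first; among all
    tets containing the point (it may lie on a shared face) the lowest tet
    index wins, deterministically.
    """
    p = np.asarray(p, float)
    tree = mesh.centroid_tree()
    n = mesh.n_elements
    k = min(32, n)
    checked: set[int] = set()
    while True:
        _, idx = tree.query(p, k=k)
        idx = np.atleast_1d(idx)
        hits = []
        for t in idx:
            t = int(t)
            if t in checked or t >= n:
                continue
            checked.add(t)
            lam = barycentric_coordinates(mesh.nodes[mesh.tets[t]], p)
            if np.all(lam >= -tol) and np.all(lam <= 1 + tol):
                hits.append((t, lam))
        if hits:
            t, lam = min(hits, key=lambda h: h[0])
            return t, np.clip(lam, 0.0, 1.0) / np.clip(lam, 0.0, 1.0).sum()
        if k >= n:
            raise OutsideMeshError(f"point {p.tolist()} outside mesh hull")
        k = min(4 * k, n)


def nearest_node(mesh, p) -> int:
    """Index of the mesh node closest to ``p`` (ties -> lowest index)."""
    p = np.asarray(p, float)
    if isinstance(mesh, HexMesh):
        pos = mesh.node_positions()
        d2 = np.einsum("ij,ij->i", pos - p, pos - p)
        return int(np.argmin(d2))  # argmin returns first (lowest) index on ties
    tree = mesh.node_tree()
    k = min(8, mesh.n_nodes)
    dist, idx = tree.query(p, k=k)
    dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    best = dist.min()
    ties = idx[dist <= best * (1 + 1e-12) + 1e-15]
    return int(ties.min())


# ---------------------------------------------------------------------------
# dihedral angles
# ---------------------------------------------------------------------------

def dihedral_angle(verts, edge: tuple[int, int]) -> float:
    """Interior dihedral angle of a tet along one of its 6 edges, in radians.

    With the edge endpoints P, Q and opposite vertices R, S, let
    ``u = Q - P``, ``v = R - P``, ``w = S - P``.  Then

        cot ϑ = ((u·u)(v·w) - (u·v)(u·w)) / (|u| |u·(v×w)|)

    which is the cotangent rule used for edge conductances.  The absolute
    value of the triple product makes the angle orientation-independent; the
    result is in (0, π), exceeding π/2 for obtuse dihedrals.
    """
    verts = np.asarray(verts, float)
    if verts.shape != (4, 3):
        raise MeshError("verts must be (4, 3)")
    i, j = edge
    if i == j or not (0 <= i < 4 and 0 <= j < 4):
        raise MeshError("edge must name two distinct vertices in 0..3")
    rest = [k for k in range(4) if k not in (i, j)]
    u = verts[j] - verts[i]
    v = verts[rest[0]] - verts[i]
    w = verts[rest[1]] - verts[i]
    triple = float(u @ np.cross(v, w))
    if triple == 0.0:
        raise MeshError("degenerate tetrahedron (zero triple product)")
    num = (u @ u) * (v @ w) - (u @ v) * (u @ w)
    den = np.linalg.norm(u) * abs(triple)
    return float(np.arctan2(den, num))


def opposite_edge(edge: tuple[int, int]) -> tuple[int, int]:
    """The tet edge sharing no vertex with ``edge`` (local indices 0..3)."""
    rest = [k for k in range(4) if k not in edge]
    return rest[0], rest[1]


# ---------------------------------------------------------------------------
# mesh file I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".msh":
        return "msh"
    if suffix in (".node", ".ele"):
        return "tetgen"
    raise MeshError(f"cannot infer mesh format from {path.name}")


def read_mesh(path, format: str | None = None) -> TetMesh:
    """Read a tetrahedral mesh from a Gmsh MSH (2.2/4.1) or TetGen file pair.

    For TetGen, pass either the ``.node`` or ``.ele`` path; the sibling file
    is found automatically.  Only 4-node tetrahedra are accepted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "msh":
        return _read_msh(path)
    if fmt == "tetgen":
        return _read_tetgen(path)
    raise MeshError(f"unsupported mesh format {fmt!r}")


def write_mesh(mesh: TetMesh, path, format: str | None = None) -> None:
    """Write a tet mesh as Gmsh MSH 2.2 or a TetGen .node/.ele pair."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "msh":
        _write_msh(mesh, path)
    elif fmt == "tetgen":
        _write_tetgen(mesh, path)
    else:
        raise MeshError(f"unsupported mesh format {fmt!r}")


def _tokens(text: str):
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            yield line


def _read_msh(path: Path) -> TetMesh:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        m = re.match(r"^\$(\w+)\s*$", lines[i])
        if m:
            name = m.group(1)
            j = i + 1
            while j < len(lines) and not lines[j].startswith(f"$End{name}"):
                j += 1
            if j >= len(lines):
                raise MeshError(f"unterminated ${name} section (line {i + 1})")
            sections[name] = lines[i + 1 : j]
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sections:
        raise MeshError("missing $MeshFormat section")
    version = sections["MeshFormat"][0].split()[0]
    if version.startswith("2"):
        return _read_msh2(sections)
    if version.startswith("4"):
        return _read_msh4(sections)
    raise MeshError(f"unsupported MSH version {version}")


def _read_msh2(sections) -> TetMesh:
    node_lines = sections["Nodes"]
    n = int(node_lines[0])
    ids = np.empty(n, np.int64)
    xyz = np.empty((n, 3))
    for k, ln in enumerate(node_lines[1 : 1 + n]):
        parts = ln.split()
        ids[k] = int(parts[0])
        xyz[k] = [float(v) for v in parts[1:4]]
    remap = {int(i): k for k, i in enumerate(ids)}
    elem_lines = sections["Elements"]
    m = int(elem_lines[0])
    tets = []
    saw_other = False
    for ln in elem_lines[1 : 1 + m]:
        parts = [int(v) for v in ln.split()]
        etype, ntags = parts[1], parts[2]
        conn = parts[3 + ntags :]
        if etype == 4:  # 4-node tetrahedron
            tets.append([remap[c] for c in conn])
        else:
            saw_other = True
    if not tets:
        raise MeshError("MSH file contains no tet4 elements")
    if saw_other:
        raise MeshError("mixed element types: only tet4 elements are accepted")
    return TetMesh(nodes=xyz, tets=np.array(tets))


def _read_msh4(sections) -> TetMesh:
    toks = list(_tokens("\n".join(sections["Nodes"])))
    header = toks[0].split()
    num_blocks, num_nodes = int(header[0]), int(header[1])
    ids: list[int] = []
    coords: list[list[float]] = []
    pos = 1
    for _ in range(num_blocks):
        blk = toks[pos].split()
        n_in_block = int(blk[3])
        pos += 1
        blk_ids = [int(toks[pos + k]) for k in range(n_in_block)]
        pos += n_in_block
        for k in range(n_in_block):
            coords.append([float(v) for v in toks[pos + k].split()[:3]])
        pos += n_in_block
        ids.extend(blk_ids)
    if len(ids) != num_nodes:
        raise MeshError("MSH4 node count mismatch")
    remap = {i: k for k, i in enumerate(ids)}

    toks = list(_tokens("\n".join(sections["Elements"])))
    header = toks[0].split()
    num_blocks = int(header[0])
    pos = 1
    tets = []
    saw_other = False
    for _ in range(num_blocks):
        blk = toks[pos].split()
        etype, n_in_block = int(blk[2]), int(blk[3])
        pos += 1
        for k in range(n_in_block):
            parts = [int(v) for v in toks[pos + k].split()]
            if etype == 4:
                tets.append([remap[c] for c in parts[1:5]])
            else:
                saw_other = True
        pos += n_in_block
    if not tets:
        raise MeshError("MSH file contains no tet4 elements")
    if saw_other:
        raise MeshError("mixed element types: only tet4 elements are accepted")
    return TetMesh(nodes=np.array(coords), tets=np.array(tets))


def _write_msh(mesh: TetMesh, path: Path) -> None:
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for k, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.append(f"{k} {x:.17g} {y:.17g} {z:.17g}")
    out += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    for k, (a, b, c, d) in enumerate(mesh.tets + 1, start=1):
        out.append(f"{k} 4 2 0 1 {a} {b} {c} {d}")
    out += ["$EndElements", ""]
    path.write_text("\n".join(out))


def _tetgen_pair(path: Path) -> tuple[Path, Path]:
    if path.suffix == ".node":
        return path, path.with_suffix(".ele")
    if path.suffix == ".ele":
        return path.with_suffix(".node"), path
    return path.with_suffix(".node"), path.with_suffix(".ele")


def _read_tetgen(path: Path) -> TetMesh:
    node_path, ele_path = _tetgen_pair(path)
    node_toks = list(_tokens(node_path.read_text()))
    header = node_toks[0].split()
    n, dim = int(header[0]), int(header[1])
    if dim != 3:
        raise MeshError(f"TetGen node file has dimension {dim}, expected 3")
    ids = np.empty(n, np.int64)
    xyz = np.empty((n, 3))
    for k, ln in enumerate(node_toks[1 : 1 + n]):
        parts = ln.split()
        ids[k] = int(parts[0])
        xyz[k] = [float(v) for v in parts[1:4]]
    remap = {int(i): k for k, i in enumerate(ids)}  # normalizes 0- or 1-based ids
    ele_toks = list(_tokens(ele_path.read_text()))
    header = ele_toks[0].split()
    m, npts = int(header[0]), int(header[1])
    if npts != 4:
        raise MeshError(f"TetGen ele file has {npts}-node elements, only tet4 accepted")
    tets = np.empty((m, 4), np.int64)
    for k, ln in enumerate(ele_toks[1 : 1 + m]):
        parts = [int(v) for v in ln.split()]
        tets[k] = [remap[c] for c in parts[1:5]]
    return TetMesh(nodes=xyz, tets=tets)


def _write_tetgen(mesh: TetMesh, path: Path) -> None:
    node_path, ele_path = _tetgen_pair(path)
    out = [f"{mesh.n_nodes} 3 0 0"]
    for k, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.append(f"{k} {x:.17g} {y:.17g} {z:.17g}")
    node_path.write_text("\n".join(out) + "\n")
    out = [f"{mesh.n_elements} 4 0"]
    for k, (a, b, c, d) in enumerate(mesh.tets + 1, start=1):
        out.append(f"{k} {a} {b} {c} {d}")
    ele_path.write_text("\n".join(out) + "\n")
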