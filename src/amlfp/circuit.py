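"""Compilation of meshes into grounded resistor networks.

A mesh plus a tissue resistivity becomes an undirected weighted graph of
inter-node conductances.  Structured cubic grids use the orthonormal edge
rule R = ρL/A; tetrahedral meshes use the cotangent (Duffin) rule
R_AB = 6 ρ tan(ϑ)/|CD|, where ϑ is the dihedral angle formed at the edge CD
opposite AB, with per-element contributions to a shared edge merged as
parallel resistors.  Hull nodes are then tied to a virtual ground through a
resistor equal to the mean of their incident edge resistances.

Coordinates arrive in μm; resistances and conductances are SI (Ω, S).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .mesh import HexMesh, MeshError, TetMesh, dihedral_angle, opposite_edge

__all__ = [
    "Medium",
    "HexEdgeSpec",
    "ResistorNetwork",
    "CircuitError",
    "hex_edge_resistance",
    "tet_edge_resistance",
    "merge_parallel",
    "assemble_network",
    "attach_ground",
    "write_netlist",
    "read_netlist",
    "export_mtx",
]

_UM = 1e-6  # μm -> m
_UM2 = 1e-12  # μm² -> m²

#: Cross-sectional area used uniformly in the constant-A compilation mode, μm².
CONSTANT_A_UM2 = 0.25


class CircuitError(ValueError):
    """Invalid medium, disconnected mesh, or malformed netlist."""


@dataclass(frozen=True)
class Medium:
    """Ohmic tissue medium: resistivity in Ω·m, scalar or per-element."""

    resistivity: float | np.ndarray = 3.8

    def __post_init__(self):
        rho = np.asarray(self.resistivity, float)
        if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
            raise CircuitError("resistivity must be positive and finite")

    @property
    def conductivity(self):
        return 1.0 / np.asarray(self.resistivity, float)

    def per_element(self, n_elements: int) -> np.ndarray:
        rho = np.asarray(self.resistivity, float)
        if rho.ndim == 0:
            return np.full(n_elements, float(rho))
        if rho.shape != (n_elements,):
            raise CircuitError(
                f"per-element resistivity has length {rho.shape}, mesh has {n_elements} elements"
            )
        return rho


@dataclass(frozen=True)
class HexEdgeSpec:
    """How cubic-lattice edges map to resistor cross-sections.

    ``continuum_A`` (default) takes A = L², giving each edge the conductance
    σ·L of the continuum-equivalent cubic lattice, so solved voltages are
    physical without a calibration step.  ``constant_A`` fixes
    A = 0.25 μm² for every mesh regardless of resolution, which reproduces
    the historical compilation but makes absolute amplitudes scale-dependent
    (a single multiplicative calibration factor recovers them).
    """

    mode: str = "continuum_A"
    constant_area: float = CONSTANT_A_UM2

    def __post_init__(self):
        if self.mode not in ("continuum_A", "constant_A"):
            raise CircuitError(f"unknown hex edge mode {self.mode!r}")

    def area(self, edge_length: float) -> float:
        """Cross-sectional area in μm² for an edge of length ``edge_length`` μm."""
        if self.mode == "continuum_A":
            return edge_length ** 2
        return self.constant_area


@dataclass
class ResistorNetwork:
    """Grounded resistor network compiled from a mesh.

    ``edges_*`` hold one merged resistor per node pair (i < j) as
    conductances in siemens; ``ground_g`` holds the per-node conductance to
    the virtual ground (0 where ungrounded).  The reduced conductance matrix
    (ground eliminated) is the weighted graph Laplacian plus the ground
    conductances on the diagonal — symmetric, and positive definite once
    every node has a path to ground.
    """

    n_nodes: int
    edges_i: np.ndarray
    edges_j: np.ndarray
    edges_g: np.ndarray
    ground_g: np.ndarray | None = None
    node_positions: np.ndarray | None = None
    hull_nodes: np.ndarray | None = None
    _matrix: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.edges_i = np.asarray(self.edges_i, np.int64)
        self.edges_j = np.asarray(self.edges_j, np.int64)
        self.edges_g = np.asarray(self.edges_g, float)
        if not (len(self.edges_i) == len(self.edges_j) == len(self.edges_g)):
            raise CircuitError("edge arrays must have equal length")
        if np.any(self.edges_i == self.edges_j):
            raise CircuitError("self-loop edge")
        lo = np.minimum(self.edges_i, self.edges_j)
        hi = np.maximum(self.edges_i, self.edges_j)
        self.edges_i, self.edges_j = lo, hi
        if self.ground_g is None:
            self.ground_g = np.zeros(self.n_nodes)
        else:
            self.ground_g = np.asarray(self.ground_g, float)

    @property
    def n_edges(self) -> int:
        return len(self.edges_g)

    @property
    def is_grounded(self) -> bool:
        return bool(np.any(self.ground_g > 0))

    def edge_conductances(self) -> dict[tuple[int, int], float]:
        return {
            (int(i), int(j)): float(g)
            for i, j, g in zip(self.edges_i, self.edges_j, self.edges_g)
        }

    def adjacency(self) -> sp.csr_matrix:
        a = sp.coo_matrix(
            (self.edges_g, (self.edges_i, self.edges_j)),
            shape=(self.n_nodes, self.n_nodes),
        )
        return (a + a.T).tocsr()

    def conductance_matrix(self) -> sp.csr_matrix:
        """Reduced nodal conductance matrix G (ground row/column eliminated)."""
        if self._matrix is None:
            a = self.adjacency()
            diag = np.asarray(a.sum(axis=1)).ravel() + self.ground_g
            self._matrix = (sp.diags(diag) - a).tocsr()
        return self._matrix

    def _invalidate(self):
        self._matrix = None


# ---------------------------------------------------------------------------
# edge resistance rules
# ---------------------------------------------------------------------------

def hex_edge_resistance(rho: float, edge_length: float, area: float) -> float:
    """R = ρL/A for a cubic-lattice edge (ρ in Ω·m, L in μm, A in μm²) -> Ω."""
    if rho <= 0 or edge_length <= 0 or area <= 0:
        raise CircuitError("resistivity, edge length and area must be positive")
    return rho * (edge_length * _UM) / (area * _UM2)


def tet_edge_resistance(rho: float, verts, edge: tuple[int, int]) -> float:
    """Cotangent-rule resistance of one tet edge (coordinates in μm) -> Ω.

    For the edge AB, the governing dihedral angle ϑ lies along the opposite
    edge CD:  R_AB = 6 ρ tan(ϑ) / |CD|.  Returns +inf (an open branch) when
    ϑ = π/2; an obtuse ϑ yields a negative resistance whose conductance
    contribution is kept in the parallel merge (see ``assemble_network``).
    """
    if rho <= 0:
        raise CircuitError("resistivity must be positive")
    verts = np.asarray(verts, float)
    opp = opposite_edge(edge)
    theta = dihedral_angle(verts, opp)
    cd = np.linalg.norm(verts[opp[1]] - verts[opp[0]])
    if cd == 0:
        raise MeshError("degenerate tetrahedron (coincident opposite-edge vertices)")
    t = np.tan(theta)
    if abs(np.cos(theta)) < 1e-15:
        return np.inf
    return 6.0 * rho * t / (cd * _UM)


def merge_parallel(resistances) -> float:
    """Total resistance of parallel resistors: 1/R = Σ 1/R_k.

    Implemented as conductance summation; +inf entries (open branches)
    contribute nothing.
    """
    r = np.asarray(list(resistances), float)
    if r.size == 0:
        raise CircuitError("cannot merge an empty set of resistors")
    g = np.where(np.isinf(r), 0.0, 1.0 / r).sum()
    return np.inf if g == 0 else 1.0 / g


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _coalesce(n_nodes, ii, jj, gg, zero_tol: float = 1e-9):
    """Merge parallel contributions per node pair (Σ conductances).

    Merged conductances whose magnitude is below ``zero_tol`` × the largest
    merged conductance are numerical zeros — edges whose element
    contributions cancel exactly in the ideal geometry (ϑ = π/2) — and are
    removed as open branches.
    """
    lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
    m = sp.coo_matrix((gg, (lo, hi)), shape=(n_nodes, n_nodes)).tocsr()
    m.sum_duplicates()
    c = m.tocoo()
    gmax = np.abs(c.data).max() if c.data.size else 0.0
    keep = np.abs(c.data) > zero_tol * gmax
    return c.row[keep], c.col[keep], c.data[keep]


def _tet_cotan_conductances(mesh: TetMesh, rho_e: np.ndarray):
    """Per-tet, per-edge conductances 1/R_AB = σ|CD|cot(ϑ_CD)/6, vectorized."""
    v = mesh.nodes[mesh.tets]  # (m, 4, 3)
    ii, jj, gg = [], [], []
    for (a, b) in TetMesh._EDGE_LOCAL:
        c, d = opposite_edge((a, b))
        # cot of the dihedral along CD, computed per element
        u = v[:, d] - v[:, c]
        p = v[:, a] - v[:, c]
        q = v[:, b] - v[:, c]
        uu = np.einsum("ij,ij->i", u, u)
        num = uu * np.einsum("ij,ij->i", p, q) - np.einsum("ij,ij->i", u, p) * np.einsum(
            "ij,ij->i", u, q
        )
        triple = np.abs(np.einsum("ij,ij->i", u, np.cross(p, q)))
        if np.any(triple == 0):
            raise MeshError("degenerate tetrahedron in mesh")
        cot = num / (np.sqrt(uu) * triple)
        cd = np.sqrt(uu) * _UM
        g = cot * cd / (6.0 * rho_e)  # siemens; zero when ϑ = π/2 exactly
        ii.append(mesh.tets[:, a])
        jj.append(mesh.tets[:, b])
        gg.append(g)
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(gg)


def assemble_network(
    mesh,
    medium: Medium,
    hex_spec: HexEdgeSpec | None = None,
    strict_obtuse: bool = False,
) -> ResistorNetwork:
    """Compile a mesh + medium into an (ungrounded) resistor network.

    Hex meshes get one resistor per lattice edge (R = ρL/A with A from
    ``hex_spec``); tet meshes get per-element cotangent-rule contributions
    merged per shared edge by parallel conductance summation.  Obtuse
    dihedral angles produce negative conductance contributions; these are
    kept (standard stiffness-matrix behavior) with a warning, or rejected
    when ``strict_obtuse`` is set.

    Raises
    ------
    CircuitError
        If the resulting graph is disconnected (component sizes listed).
    """
    if isinstance(mesh, HexMesh):
        spec = hex_spec or HexEdgeSpec()
        rho = np.asarray(medium.resistivity, float)
        edges = mesh.edges()
        if rho.ndim == 0:
            r = hex_edge_resistance(float(rho), mesh.edge_length, spec.area(mesh.edge_length))
            gg = np.full(len(edges), 1.0 / r)
        else:
            rho_e = medium.per_element(mesh.n_elements)
            rho_edge = _hex_edge_resistivity(mesh, rho_e)
            area = spec.area(mesh.edge_length)
            gg = area * _UM2 / (rho_edge * mesh.edge_length * _UM)
        ii, jj = edges[:, 0], edges[:, 1]
    elif isinstance(mesh, TetMesh):
        rho_e = medium.per_element(mesh.n_elements)
        ii, jj, gg = _tet_cotan_conductances(mesh, rho_e)
    else:
        raise CircuitError(f"cannot assemble a network from {type(mesh).__name__}")

    ii, jj, gg = _coalesce(mesh.n_nodes, ii, jj, gg)
    n_neg = int(np.sum(gg < 0))
    if n_neg:
        msg = f"{n_neg} merged edge conductances are negative (obtuse dihedral angles)"
        if strict_obtuse:
            raise CircuitError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    net = ResistorNetwork(
        n_nodes=mesh.n_nodes,
        edges_i=ii,
        edges_j=jj,
        edges_g=gg,
        node_positions=mesh.node_positions(),
        hull_nodes=mesh.hull_nodes(),
    )
    adj = net.adjacency()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise CircuitError(
            f"mesh compiles to a disconnected network: {n_comp} components of sizes {sizes.tolist()}"
        )
    return net


def _hex_edge_resistivity(mesh: HexMesh, rho_e: np.ndarray) -> np.ndarray:
    """Per-edge resistivity for a hex grid: mean over voxels incident to the edge."""
    nx, ny, nz = mesh.dims
    vox = rho_e.reshape(nz - 1, ny - 1, nx - 1)  # [iz, iy, ix]
    pad = np.full((nz + 1, ny + 1, nx + 1), np.nan)
    pad[1:nz, 1:ny, 1:nx] = vox.transpose(0, 1, 2)
    # For an x-edge at (ix..ix+1, iy, iz) the incident voxels are the up-to-4
    # voxels (ix, iy-{0,1}, iz-{0,1}); analogous for y and z edges.
    out = []
    for axis in range(3):
        if axis == 0:
            stacks = [pad[iz0 + 1 : iz0 + nz, iy0 + 1 : iy0 + ny, 1:nx] for iz0 in (-1, 0) for iy0 in (-1, 0)]
        elif axis == 1:
            stacks = [pad[iz0 + 1 : iz0 + nz, 1:ny, ix0 + 1 : ix0 + nx] for iz0 in (-1, 0) for ix0 in (-1, 0)]
        else:
            stacks = [pad[1:nz, iy0 + 1 : iy0 + ny, ix0 + 1 : ix0 + nx] for iy0 in (-1, 0) for ix0 in (-1, 0)]
        s = np.stack(stacks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(s, axis=0)
        out.append(mean.ravel())
    return np.concatenate(out)


def attach_ground(network: ResistorNetwork) -> ResistorNetwork:
    """Tie every hull node to virtual ground.

    Each hull node receives one ground resistor whose resistance equals the
    arithmetic mean of the resistances of its incident (merged) mesh edges.
    Incident edges with non-positive conductance (obtuse-element artifacts)
    are excluded from the average — their resistances are not meaningful as
    wires.  Returns a new network; the input is unchanged.
    """
    if network.hull_nodes is None:
        raise CircuitError("network does not record hull nodes; assemble from a mesh first")
    hull = np.asarray(network.hull_nodes, np.int64)
    ground_g = np.array(network.ground_g, float, copy=True)
    # mean incident resistance per node, via sums over the edge list
    r_sum = np.zeros(network.n_nodes)
    r_cnt = np.zeros(network.n_nodes, np.int64)
    pos = network.edges_g > 0
    with np.errstate(divide="ignore"):
        r_edge = np.where(pos, 1.0 / network.edges_g, 0.0)
    for nodes in (network.edges_i[pos], network.edges_j[pos]):
        np.add.at(r_sum, nodes, r_edge[pos])
        np.add.at(r_cnt, nodes, 1)
    if np.any(r_cnt[hull] == 0):
        bad = hull[r_cnt[hull] == 0]
        raise CircuitError(f"isolated hull nodes with no incident edges: {bad[:10].tolist()}")
    ground_g[hull] = r_cnt[hull] / r_sum[hull]  # 1 / mean(R)
    return replace(network, ground_g=ground_g, _matrix=None)


# ---------------------------------------------------------------------------
# netlist I/O
# ---------------------------------------------------------------------------

def write_netlist(network: ResistorNetwork, injected_currents, path) -> None:
    """Write a SPICE-style netlist: resistors, ground links, current sources.

    Internal node ``i`` becomes netlist node ``i+1``; ground is node 0.
    Injections are given per node in nA and written in amperes as
    ``I<k> 0 <node> <amps>`` (current pushed from ground into the node).
    """
    inj = np.asarray(injected_currents, float)
    if inj.shape != (network.n_nodes,):
        raise CircuitError("injected_currents must have one entry per node")
    lines = [f"* admittance-method netlist: {network.n_nodes} nodes"]
    k = 0
    for i, j, g in zip(network.edges_i, network.edges_j, network.edges_g):
        k += 1
        lines.append(f"R{k} {i + 1} {j + 1} {1.0 / g:.12e}")
    for i in np.nonzero(network.ground_g > 0)[0]:
        k += 1
        lines.append(f"R{k} {i + 1} 0 {1.0 / network.ground_g[i]:.12e}")
    ks = 0
    for i in np.nonzero(inj != 0)[0]:
        ks += 1
        lines.append(f"I{ks} 0 {i + 1} {inj[i] * 1e-9:.12e}")
    Path(path).write_text("\n".join(lines) + "\n")


_NETLIST_RE = re.compile(r"^([RI])(\d+)\s+(\d+)\s+(\d+)\s+([-+0-9.eE]+)\s*$")


def read_netlist(path) -> tuple[ResistorNetwork, np.ndarray]:
    """Read a netlist written by :func:`write_netlist`.

    Returns the network (without node positions) and the per-node injection
    vector in nA.  Ground is netlist node 0.
    """
    res: list[tuple[int, int, float]] = []
    gnd: list[tuple[int, float]] = []
    inj: list[tuple[int, float]] = []
    max_node = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("*"):
            continue
        m = _NETLIST_RE.match(line)
        if not m:
            raise CircuitError(f"malformed netlist line {lineno}: {raw!r}")
        kind, _, a, b, val = m.groups()
        a, b, val = int(a), int(b), float(val)
        max_node = max(max_node, a, b)
        if kind == "R":
            if a == 0 and b == 0:
                raise CircuitError(f"resistor to ground on both ends at line {lineno}")
            if a == 0 or b == 0:
                gnd.append((max(a, b) - 1, 1.0 / val))
            else:
                res.append((a - 1, b - 1, 1.0 / val))
        else:
            if a != 0:
                raise CircuitError(f"current source must reference ground at line {lineno}")
            inj.append((b - 1, val * 1e9))
    n = max_node
    declared = set()
    for i, j, _ in res:
        declared.update((i, j))
    declared.update(i for i, _ in gnd)
    for i, _ in inj:
        if i not in declared:
            raise CircuitError(f"current source references undeclared node {i + 1}")
    ii = np.array([r[0] for r in res], np.int64)
    jj = np.array([r[1] for r in res], np.int64)
    gg = np.array([r[2] for r in res], float)
    ground_g = np.zeros(n)
    for i, g in gnd:
        ground_g[i] += g
    currents = np.zeros(n)
    for i, v in inj:
        currents[i] += v
    return ResistorNetwork(n, ii, jj, gg, ground_g=ground_g), currents


def export_mtx(network: ResistorNetwork, path) -> None:
    """Export the reduced conductance matrix as symmetric MatrixMarket."""
    from scipy.io import mmwrite

    g = sp.tril(network.conductance_matrix())
    mmwrite(Path(path), g, symmetry="symmetric")
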