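"""Coupling of off-node current sources to mesh nodes, and back.

Neuronal compartment currents rarely sit on mesh nodes.  Two alignment
strategies are supported:

* **splitting** — distribute each source over the corner nodes of the
  element that contains it, using trilinear (hex) or barycentric (tet)
  partition-of-unity weights;
* **shifting** — assign each source wholly to its nearest mesh node.

The same element-wise weights interpolate solved nodal voltages back to
arbitrary points, which closes the loop for bidirectional coupling with a
compartment model: solve the field, read it at each compartment, apply it as
an extracellular potential offset, advance the membrane model one step, and
feed the new transmembrane currents back into the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mesh import HexMesh, OutsideMeshError, TetMesh, locate_hex_voxel, locate_tet, nearest_node
from .solver import FieldSolution, SolverError, solve_frame

__all__ = [
    "CurrentSourceSeries",
    "NodeAssignment",
    "split_weights_hex",
    "split_weights_tet",
    "assign_sources",
    "interpolate_potential",
    "run_bidirectional",
]


@dataclass
class CurrentSourceSeries:
    """Point current sources over time: positions (μm) and amplitudes (nA).

    ``amplitudes[i, t]`` is the current of source ``i`` at time step ``t``;
    positive amplitude means current injected into the extracellular network
    (outward transmembrane current).
    """

    positions: np.ndarray  # (n_sources, 3), μm
    amplitudes: np.ndarray  # (n_sources, n_timesteps), nA
    dt: float = 0.1  # ms
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, float))
        if self.positions.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("positions and amplitudes disagree on source count")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.cell_ids is not None:
            self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timesteps) * self.dt

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write ``x,y,z[,cell_id],t0,t1,...`` (μm, nA)."""
        cols = {"x": self.positions[:, 0], "y": self.positions[:, 1],
                "z": self.positions[:, 2]}
        if self.cell_ids is not None:
            cols["cell_id"] = self.cell_ids
        for t in range(self.n_timesteps):
            cols[f"t{t}"] = self.amplitudes[:, t]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt: float = 0.1) -> "CurrentSourceSeries":
        df = pd.read_csv(path)
        for c in ("x", "y", "z"):
            if c not in df.columns:
                raise ValueError(f"source CSV missing column {c!r}")
        tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
        tcols.sort(key=lambda c: int(c[1:]))
        if not tcols:
            raise ValueError("source CSV has no time-step columns t0, t1, ...")
        cell_ids = df["cell_id"].to_numpy() if "cell_id" in df.columns else None
        return cls(
            positions=df[["x", "y", "z"]].to_numpy(float),
            amplitudes=df[tcols].to_numpy(float),
            dt=dt,
            cell_ids=cell_ids,
        )

    def to_json(self, path) -> None:
        payload = {
            "dt_ms": self.dt,
            "positions_um": self.positions.tolist(),
            "amplitudes_nA": self.amplitudes.tolist(),
        }
        if self.cell_ids is not None:
            payload["cell_ids"] = np.asarray(self.cell_ids).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "CurrentSourceSeries":
        payload = json.loads(Path(path).read_text())
        return cls(
            positions=np.array(payload["positions_um"], float),
            amplitudes=np.array(payload["amplitudes_nA"], float),
            dt=float(payload["dt_ms"]),
            cell_ids=np.array(payload["cell_ids"]) if "cell_ids" in payload else None,
        )


@dataclass
class NodeAssignment:
    """Time-invariant mapping of sources onto mesh nodes.

    Flat triplet representation: entry ``k`` says source ``source_idx[k]``
    deposits fraction ``weight[k]`` of its current on node ``node[k]``.
    Weights are non-negative and sum to 1 per source; shifting uses a single
    weight of 1, splitting at most 8 (hex) or 4 (tet) entries.
    """

    method: str
    n_sources: int
    source_idx: np.ndarray
    node: np.ndarray
    weight: np.ndarray
    _P: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.source_idx = np.asarray(self.source_idx, np.int64)
        self.node = np.asarray(self.node, np.int64)
        self.weight = np.asarray(self.weight, float)
        if np.any(self.weight < -1e-15):
            raise ValueError("assignment weights must be non-negative")
        sums = np.bincount(self.source_idx, weights=self.weight, minlength=self.n_sources)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("assignment weights must sum to 1 per source")

    def injection_matrix(self, n_nodes: int) -> sp.csr_matrix:
        """Sparse (n_nodes × n_sources) operator turning amplitudes into nodal nA."""
        if self._P is None or self._P.shape[0] != n_nodes:
            self._P = sp.coo_matrix(
                (self.weight, (self.node, self.source_idx)),
                shape=(n_nodes, self.n_sources),
            ).tocsr()
        return self._P

    def nodal_injections(self, amplitudes_nA) -> np.ndarray:
        """Apply the assignment to one amplitude column (or matrix), in nA."""
        amp = np.asarray(amplitudes_nA, float)
        n_nodes = int(self.node.max()) + 1 if self._P is None else self._P.shape[0]
        return self.injection_matrix(n_nodes) @ amp

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"source": self.source_idx, "node": self.node, "weight": self.weight}
        ).to_csv(path, index=False)


def split_weights_hex(local, tol: float = 1e-9) -> np.ndarray:
    """Trilinear corner weights for local voxel coordinates in [0, 1]³.

    Corner ordering matches :func:`amlfp.mesh.locate_hex_voxel` (corner bits
    dx + 2dy + 4dz).  The weights form an exact partition of unity.
    """
    t = np.asarray(local, float)
    if t.shape != (3,):
        raise ValueError("local coordinates must be length 3")
    if np.any(t < -tol) or np.any(t > 1 + tol):
        raise ValueError(f"local coordinates {t.tolist()} outside the unit cube")
    t = np.clip(t, 0.0, 1.0)
    w = np.empty(8)
    for k in range(8):
        dx, dy, dz = k & 1, (k >> 1) & 1, (k >> 2) & 1
        w[k] = (t[0] if dx else 1 - t[0]) * (t[1] if dy else 1 - t[1]) * (t[2] if dz else 1 - t[2])
    return w


def split_weights_tet(bary, tol: float = 1e-9) -> np.ndarray:
    """Tet corner weights: the barycentric coordinates themselves."""
    lam = np.asarray(bary, float)
    if lam.shape != (4,):
        raise ValueError("barycentric coordinates must be length 4")
    if abs(lam.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError("barycentric coordinates must sum to 1")
    if np.any(lam < -tol):
        raise ValueError("barycentric coordinates must be non-negative")
    lam = np.clip(lam, 0.0, None)
    return lam / lam.sum()


def assign_sources(mesh, series: CurrentSourceSeries, method: str = "split") -> NodeAssignment:
    """Map every source of ``series`` onto mesh nodes by splitting or shifting.

    The assignment depends only on geometry and is reused for every time
    step.  Sources outside the mesh hull raise, listing the offending source
    indices — sources are never silently dropped.
    """
    if method not in ("split", "shift"):
        raise ValueError(f"unknown method {method!r}; use 'split' or 'shift'")
    src, nod, wgt = [], [], []
    outside = []
    for s in range(series.n_sources):
        p = series.positions[s]
        try:
            if method == "shift":
                nodes = np.array([nearest_node(mesh, p)])
                weights = np.array([1.0])
            elif isinstance(mesh, HexMesh):
                nodes, local = locate_hex_voxel(mesh, p)
                weights = split_weights_hex(local)
            else:
                t, lam = locate_tet(mesh, p)
                nodes = mesh.tets[t]
                weights = split_weights_tet(lam)
        except OutsideMeshError:
            outside.append(s)
            continue
        keep = weights > 0
        nodes, weights = nodes[keep], weights[keep]
        weights = weights / weights.sum()
        src.extend([s] * len(nodes))
        nod.extend(nodes.tolist())
        wgt.extend(weights.tolist())
    if outside:
        raise OutsideMeshError(f"sources outside mesh hull: indices {outside}")
    return NodeAssignment(
        method=method,
        n_sources=series.n_sources,
        source_idx=np.array(src),
        node=np.array(nod),
        weight=np.array(wgt),
    )


def interpolate_potential(mesh, nodal_voltages, p):
    """Voltage at an arbitrary point from nodal voltages.

    Trilinear within the containing voxel (hex) or barycentric within the
    containing tet.  ``nodal_voltages`` may be a vector (one frame) or an
    (n_nodes, T) matrix; the result mirrors its trailing shape.  Exact at
    nodes by partition of unity.
    """
    v = np.asarray(nodal_voltages, float)
    if isinstance(mesh, HexMesh):
        nodes, local = locate_hex_voxel(mesh, p)
        w = split_weights_hex(local)
    else:
        t, lam = locate_tet(mesh, p)
        nodes, w = mesh.tets[t], split_weights_tet(lam)
    return w @ v[nodes]


def run_bidirectional(network, mesh, model, n_steps: int, dt: float,
                      tolerance: float = 1e-9):
    """Staggered bidirectional coupling between network and compartment model.

    Per step: solve the admittance network for the model's present
    transmembrane currents, interpolate the solved field at every
    compartment, apply those voltages to the model as extracellular
    potential offsets (an "extracellular battery"), then advance the model
    one step of ``dt`` and carry its new currents into the next frame.  The
    source→node assignment is computed once from the compartment positions.

    The model must expose ``positions() -> (n, 3) μm``,
    ``currents() -> (n,) nA``, ``apply_extracellular(voltages_mV)`` and
    ``step(dt_ms)``.

    Returns
    -------
    (FieldSolution, trace)
        ``trace`` is the (n_compartments, n_steps) matrix of the currents
        the model emitted at each solved step.
    """
    positions = np.asarray(model.positions(), float)
    probe = CurrentSourceSeries(positions=positions,
                                amplitudes=np.zeros((len(positions), 1)), dt=dt)
    assignment = assign_sources(mesh, probe, method="split")
    P = assignment.injection_matrix(network.n_nodes)

    voltages = np.empty((network.n_nodes, n_steps))
    trace = np.empty((len(positions), n_steps))
    reports = []
    x0 = None
    for t in range(n_steps):
        currents = np.asarray(model.currents(), float)
        if not np.all(np.isfinite(currents)):
            raise SolverError(f"model emitted non-finite currents at step {t}")
        trace[:, t] = currents
        v, rep = solve_frame(network, P @ currents, tolerance=tolerance, x0=x0)
        voltages[:, t] = v
        reports.append(rep)
        x0 = v
        phi = np.array([interpolate_potential(mesh, v, p) for p in positions])
        model.apply_extracellular(phi)
        model.step(dt)
    return FieldSolution(voltages=voltages, reports=reports), trace
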