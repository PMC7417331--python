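"""Sparse solution of nodal voltages in the grounded resistor network.

Each time step is a linear system G v = i, where G is the reduced nodal
conductance matrix (ground eliminated — symmetric positive definite once
the hull is grounded), i the vector of injected node currents, and v the
nodal voltages.  Frames are solved by preconditioned conjugate gradients
with the previous frame as warm start; a dense direct solve is available as
an independent oracle for tests.

Unit convention at the solver boundary: conductances in S, injections in nA
(converted to A internally), voltages returned in mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["SolverError", "SolveReport", "FieldSolution", "solve_frame", "solve_series",
           "dense_solve"]

_NA_TO_A = 1e-9
_V_TO_MV = 1e3


class SolverError(RuntimeError):
    """Singular/non-SPD system or non-convergence."""


@dataclass(frozen=True)
class SolveReport:
    iterations: int
    residual: float
    tolerance: float

    def to_dict(self):
        return {"iterations": self.iterations, "residual": self.residual,
                "tolerance": self.tolerance}


@dataclass
class FieldSolution:
    """Nodal voltages per time step (mV), with per-step solver reports."""

    voltages: np.ndarray  # (n_nodes, n_timesteps), mV
    reports: list[SolveReport]

    @property
    def n_nodes(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.voltages.shape[1]


def _system(network):
    g = network.conductance_matrix()
    if not network.is_grounded:
        raise SolverError("network has no ground links; the system is singular")
    return g


def solve_frame(network, injections_nA, tolerance: float = 1e-9,
                maxiter: int | None = None, x0=None):
    """Solve one frame G v = i.

    Parameters
    ----------
    injections_nA : array (n_nodes,)
        Current injected into each node, nA (positive into the network).
    tolerance : float
        Relative residual ‖Gv − i‖/‖i‖ required of the solution.
    x0 : array, optional
        Warm-start voltages in mV (e.g. the previous frame).

    Returns
    -------
    (voltages_mV, report)
    """
    g = _system(network)
    i = np.asarray(injections_nA, float)
    if i.shape != (network.n_nodes,):
        raise SolverError("injection vector length must equal node count")
    if not np.all(np.isfinite(i)):
        raise SolverError("non-finite injections")
    b = i * _NA_TO_A
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros(network.n_nodes), SolveReport(0, 0.0, tolerance)

    diag = g.diagonal()
    if np.any(diag <= 0):
        raise SolverError("conductance matrix has non-positive diagonal (non-SPD)")
    precond = spla.LinearOperator(g.shape, matvec=lambda x: x / diag)
    if maxiter is None:
        maxiter = max(10 * network.n_nodes, 100)

    it = 0

    def _count(_):
        nonlocal it
        it += 1

    x0_V = None if x0 is None else np.asarray(x0, float) / _V_TO_MV
    v, info = spla.cg(g, b, x0=x0_V, rtol=tolerance, atol=0.0, maxiter=maxiter,
                      M=precond, callback=_count)
    residual = float(np.linalg.norm(g @ v - b) / bnorm)
    if info != 0 or not np.all(np.isfinite(v)):
        raise SolverError(
            f"conjugate gradients failed to converge (info={info}, residual={residual:.3e})"
        )
    return v * _V_TO_MV, SolveReport(it, residual, tolerance)


def solve_series(network, assignment, series, tolerance: float = 1e-9,
                 maxiter: int | None = None, warm_start: bool = True) -> FieldSolution:
    """Solve all time steps of a current-source series.

    The (time-invariant) node assignment maps source amplitudes onto nodal
    injections for every step; each frame is solved with the previous frame's
    voltages as warm start.
    """
    inj = assignment.injection_matrix(network.n_nodes) @ series.amplitudes  # (n_nodes, T), nA
    n_steps = inj.shape[1]
    voltages = np.empty((network.n_nodes, n_steps))
    reports = []
    x0 = None
    for t in range(n_steps):
        try:
            v, rep = solve_frame(network, inj[:, t], tolerance=tolerance,
                                 maxiter=maxiter, x0=x0)
        except SolverError as exc:
            raise SolverError(f"time step {t}: {exc}") from exc
        voltages[:, t] = v
        reports.append(rep)
        if warm_start:
            x0 = v
    return FieldSolution(voltages=voltages, reports=reports)


def dense_solve(network, injections_nA) -> np.ndarray:
    """Dense direct solution (LAPACK) — the independent oracle for tests."""
    g = _system(network).toarray()
    b = np.asarray(injections_nA, float) * _NA_TO_A
    try:
        v = np.linalg.solve(g, b)
    except np.linalg.LinAlgError as exc:
        raise SolverError(f"singular system: {exc}") from exc
    return v * _V_TO_MV
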