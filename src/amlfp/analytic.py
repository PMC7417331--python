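"""Analytic point-source LFP estimates — the proxy ground truth.

In an infinite, homogeneous, isotropic volume conductor the extracellular
potential of a monopolar point current source is

    φ(r) = ρ I / (4 π r)

and fields of many sources superpose linearly.  With ρ in Ω·m, I in nA and
r in μm this expression yields millivolts directly, which is the unit
convention used throughout the package.  These analytic estimates serve as
the reference against which every numerical (resistor-network) solution is
validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "RecordingGrid",
    "SingularityError",
    "distance",
    "point_source_potential",
    "analytic_lfp",
]

#: Default singularity guard: recording points closer than this (μm) to a
#: source are rejected rather than producing unboundedly large potentials.
DEFAULT_R_MIN = 1.0


class SingularityError(ValueError):
    """A recording point is too close to a point source."""


@dataclass
class RecordingGrid:
    """A set of virtual recording locations (μm), typically a planar grid."""

    points: np.ndarray
    layout: dict | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.points.shape[1] != 3:
            raise ValueError("recording points must be (n, 3)")
        uniq = np.unique(self.points, axis=0)
        if len(uniq) != len(self.points):
            raise ValueError("recording points must be distinct")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.points, columns=["x", "y", "z"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RecordingGrid":
        df = pd.read_csv(path)
        return cls(points=df[["x", "y", "z"]].to_numpy(float))


def distance(p, q) -> float:
    """Euclidean source-to-recording-point distance in μm."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def point_source_potential(current_nA, rho: float, r_um, r_min: float = DEFAULT_R_MIN):
    """φ = ρ I / (4πr) in mV (ρ in Ω·m, I in nA, r in μm).

    Raises :class:`SingularityError` for any distance at or below ``r_min``.
    """
    r = np.asarray(r_um, float)
    if np.any(r <= r_min):
        raise SingularityError(f"distance {r.min()} μm at or below the guard {r_min} μm")
    return np.asarray(current_nA, float) * rho / (4.0 * np.pi * r)


def analytic_lfp(series, grid: RecordingGrid, rho: float = 3.8,
                 r_min: float = DEFAULT_R_MIN) -> np.ndarray:
    """Superposed point-source potentials at every grid point and time step.

    Returns an (n_points, n_timesteps) matrix in mV whose entry (p, t) is
    the sum over sources i of ρ I_i(t) / (4π r_ip).
    """
    d = cdist(grid.points, series.positions)
    if np.any(d <= r_min):
        p, s = np.unravel_index(np.argmin(d), d.shape)
        raise SingularityError(
            f"recording point {p} is {d[p, s]:.3g} μm from source {s} "
            f"(singularity guard {r_min} μm)"
        )
    kernel = rho / (4.0 * np.pi * d)  # mV per nA
    return kernel @ series.amplitudes
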