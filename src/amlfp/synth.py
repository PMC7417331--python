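"""Synthetic laminar current-source populations and toy compartment models.

Real evoked-potential source data come from compartmental network
simulations: thousands of per-compartment transmembrane currents that are
charge balanced within each cell (what leaves a soma enters its dendrites
and vice versa), arranged in a laminar sheet, with a brief stimulation
artifact followed by a population-spike/after-hyperpolarization response.
This module generates populations with that structure — laminar sink/source
dipole cells, an artifact window, a biphasic response waveform, per-cell
timing jitter, optional noise — so the full meshing → circuit → solve →
compare pipeline can be exercised and tested without a network simulator.
It makes no claim of biological fidelity beyond this qualitative structure.

Also provided: a passive linear multi-compartment toy cell that fulfils the
bidirectional-coupling model contract (positions / currents /
apply_extracellular / step), for testing the field-feedback loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analytic import RecordingGrid
from .coupling import CurrentSourceSeries

__all__ = [
    "PopulationSpec",
    "generate_population",
    "ToyCompartmentModel",
    "make_toy_model",
    "make_recording_grid",
]


@dataclass
class PopulationSpec:
    """Parameters of a synthetic laminar source population.

    The somata sit on a regular grid in the plane z = 0 spanning
    ``extent × extent`` μm²; each cell's dendritic cable rises in +z over
    ``dendrite_extent`` μm, divided into ``n_compartments - 1`` dendritic
    compartments plus the somatic compartment.  Timing is in ms from the
    virtual stimulus: a large brief artifact in ``artifact_window`` and a
    biphasic response (negative population-spike lobe then positive
    after-hyperpolarization lobe) in ``response_window``.
    """

    n_cells: int = 16
    extent: float = 400.0          # μm, lateral span of the soma sheet
    dendrite_extent: float = 300.0  # μm
    n_compartments: int = 5
    duration: float = 15.0         # ms
    dt: float = 0.25               # ms
    artifact_window: tuple[float, float] = (0.0, 2.0)   # ms
    response_window: tuple[float, float] = (3.0, 12.0)  # ms
    peak_amplitude: float = 50.0   # nA, somatic peak of the response phase
    artifact_amplitude: float = 500.0  # nA, somatic peak of the artifact phase
    noise_sd: float = 0.0          # nA, added to dendritic currents
    latency_jitter: float = 0.4    # ms sd of per-cell response latency
    include_artifact: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_compartments < 2:
            raise ValueError("need at least a soma and one dendritic compartment")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        for w in (self.artifact_window, self.response_window):
            if not (0 <= w[0] < w[1] <= self.duration):
                raise ValueError(f"window {w} outside series duration {self.duration}")
        if self.dendrite_extent <= 0:
            raise ValueError("dendrite_extent must be positive")

    @property
    def n_timesteps(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timesteps) * self.dt


def _gamma_lobe(t, onset, rise, decay):
    """Smooth unit-peak lobe: (t')^a exp(-t'/b) shape, zero before onset."""
    s = np.clip(t - onset, 0.0, None)
    shape = (s / rise) ** 2 * np.exp(-s / decay)
    peak = shape.max()
    return shape / peak if peak > 0 else shape


def response_waveform(times, window, jitter: float = 0.0):
    """Biphasic evoked-response envelope for the somatic current.

    Negative (population-spike) lobe early in the window, positive
    (after-hyperpolarization) lobe late, unit negative peak.
    """
    t0, t1 = window
    span = t1 - t0
    spike = _gamma_lobe(times, t0 + jitter, 0.25 * span, 0.12 * span)
    ahp = _gamma_lobe(times, t0 + jitter + 0.35 * span, 0.5 * span, 0.3 * span)
    w = -spike + 0.45 * ahp
    w[times > t1 + 2.0] *= 0.0  # ensure the envelope dies after the window
    return w


def artifact_waveform(times, window):
    """Brief biphasic stimulation-artifact envelope, unit positive peak."""
    t0, t1 = window
    mid = 0.5 * (t0 + t1)
    width = 0.18 * (t1 - t0)
    pos = np.exp(-0.5 * ((times - t0 - 0.25 * (t1 - t0)) / width) ** 2)
    neg = np.exp(-0.5 * ((times - mid - 0.25 * (t1 - t0)) / width) ** 2)
    w = pos - neg
    w[(times < t0) | (times > t1)] = 0.0
    return w


def generate_population(spec: PopulationSpec) -> CurrentSourceSeries:
    """Generate a charge-balanced laminar population source series.

    Each cell contributes its somatic compartment (carrying the response
    waveform, negative during the population spike) and dendritic
    compartments carrying the opposite current distributed along the cable,
    so the per-cell sum of currents is exactly zero at every time step.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times
    n_side = int(np.ceil(np.sqrt(spec.n_cells)))
    pitch = spec.extent / max(n_side - 1, 1)
    cells = []
    for c in range(spec.n_cells):
        gx, gy = c % n_side, c // n_side
        soma = np.array([gx * pitch, gy * pitch, 0.0])
        if n_side > 1:
            soma[:2] += rng.uniform(-0.2, 0.2, size=2) * pitch
        soma[:2] = np.clip(soma[:2], 0.0, spec.extent)  # stay in the laminar envelope
        cells.append(soma)

    n_dend = spec.n_compartments - 1
    dz = spec.dendrite_extent / n_dend
    positions, amplitudes, cell_ids = [], [], []
    for c, soma in enumerate(cells):
        jit = rng.normal(0.0, spec.latency_jitter)
        gain = rng.uniform(0.8, 1.2)
        env = spec.peak_amplitude * gain * response_waveform(times, spec.response_window, jit)
        if spec.include_artifact:
            env = env + spec.artifact_amplitude * gain * artifact_waveform(
                times, spec.artifact_window
            )
        # dendritic share of the return current decays with distance from soma
        share = np.exp(-np.arange(1, n_dend + 1) / max(n_dend / 2.0, 1.0))
        share /= share.sum()
        dend_amp = -share[:, None] * env[None, :]
        if spec.noise_sd > 0:
            dend_amp = dend_amp + rng.normal(0.0, spec.noise_sd, size=dend_amp.shape)
        soma_amp = -dend_amp.sum(axis=0)  # exact per-cell charge balance
        positions.append(soma)
        amplitudes.append(soma_amp)
        cell_ids.append(c)
        for k in range(n_dend):
            positions.append(soma + np.array([0.0, 0.0, (k + 1) * dz]))
            amplitudes.append(dend_amp[k])
            cell_ids.append(c)

    return CurrentSourceSeries(
        positions=np.array(positions),
        amplitudes=np.array(amplitudes),
        dt=spec.dt,
        cell_ids=np.array(cell_ids),
    )


class ToyCompartmentModel:
    """Passive linear multi-compartment cells for coupling tests.

    Each cell is a chain of compartments with membrane capacitance ``cm``
    (nF), leak conductance ``gl`` (μS) and axial conductance ``ga`` (μS)
    between neighbours.  State is the membrane potential V_m (mV) of each
    compartment; the intracellular potential is V_m + V_e, where V_e is the
    extracellular potential applied from the field solution.  Axial currents
    respond to intracellular gradients, so a spatially uniform V_e leaves
    the dynamics unchanged.  The transmembrane current a compartment passes
    to the extracellular space equals the net axial current entering it plus
    any injected drive, keeping each cell charge balanced.

    Integration is forward Euler in :meth:`step` (adequate for the smooth,
    well-resolved passive dynamics used in tests; the coupling loop is
    integrator-agnostic).
    """

    def __init__(self, positions, cm=0.01, gl=0.001, ga=0.05,
                 cell_ids=None, drive=None, v_rest=0.0):
        self.pos = np.atleast_2d(np.asarray(positions, float))
        n = len(self.pos)
        self.cell_ids = np.zeros(n, int) if cell_ids is None else np.asarray(cell_ids, int)
        self.cm, self.gl, self.ga = float(cm), float(gl), float(ga)
        self.vm = np.full(n, float(v_rest))
        self.ve = np.zeros(n)
        self.t = 0.0
        # drive(t) -> per-compartment injected current in nA (intracellular)
        self.drive = drive if drive is not None else (lambda t: np.zeros(n))
        # axial neighbour pairs: consecutive compartments within a cell
        pairs = []
        for cid in np.unique(self.cell_ids):
            idx = np.nonzero(self.cell_ids == cid)[0]
            pairs.extend(zip(idx[:-1], idx[1:]))
        self.pairs = np.array(pairs, int).reshape(-1, 2)

    # -- contract ----------------------------------------------------------
    def positions(self):
        return self.pos

    def _axial_in(self):
        """Net axial current entering each compartment, nA (μS × mV = nA)."""
        inflow = np.zeros(len(self.pos))
        if len(self.pairs):
            vi = self.vm + self.ve
            i_ab = self.ga * (vi[self.pairs[:, 0]] - vi[self.pairs[:, 1]])
            np.subtract.at(inflow, self.pairs[:, 0], i_ab)
            np.add.at(inflow, self.pairs[:, 1], i_ab)
        return inflow

    def currents(self):
        """Transmembrane currents passed to the extracellular space, nA.

        Equals the net current arriving intracellularly (axial + drive);
        sums to zero within each cell up to the injected drive's own sum.
        """
        return self._axial_in() + self.drive(self.t)

    def apply_extracellular(self, voltages_mV):
        self.ve = np.asarray(voltages_mV, float)

    def step(self, dt_ms: float):
        i_in = self._axial_in() + self.drive(self.t)
        dvm = (i_in - self.gl * self.vm) / self.cm  # mV/ms  (nA / nF)
        self.vm = self.vm + dt_ms * dvm
        self.t += dt_ms


def make_toy_model(spec: PopulationSpec | None = None, n_cells: int = 2,
                   n_compartments: int = 2, spacing: float = 100.0,
                   drive_amplitude: float = 1.0, **kwargs) -> ToyCompartmentModel:
    """Build a small passive compartment-model instance for coupling tests.

    Cells are vertical two-or-more-compartment cables on a line in x; a
    sinusoidal dipolar drive (+I at the soma, −I at the distal tip, so each
    cell stays charge balanced) produces a nonzero free-running trace.
    Pass a :class:`PopulationSpec` to take geometry from it instead.
    """
    if spec is not None:
        n_cells = spec.n_cells
        n_compartments = spec.n_compartments
        spacing = spec.extent / max(n_cells - 1, 1) if spec.n_cells > 1 else spec.extent
        dz = spec.dendrite_extent / (n_compartments - 1)
    else:
        dz = spacing
    positions, cell_ids = [], []
    for c in range(n_cells):
        for k in range(n_compartments):
            positions.append([c * spacing, 0.0, k * dz])
            cell_ids.append(c)
    positions = np.array(positions, float)
    cell_ids = np.array(cell_ids)

    comp_idx = np.arange(len(positions)) % n_compartments

    def drive(t, _n=len(positions), _soma=(comp_idx == 0),
              _tip=(comp_idx == n_compartments - 1)):
        out = np.zeros(_n)
        amp = drive_amplitude * np.sin(2 * np.pi * t / 5.0)
        out[_soma] = amp
        out[_tip] -= amp
        return out

    return ToyCompartmentModel(positions, cell_ids=cell_ids, drive=drive, **kwargs)


def make_recording_grid(plane_offset: float = -50.0, nx: int = 26, ny: int = 47,
                        extent: tuple[float, float] = (400.0, 760.0),
                        origin: tuple[float, float] = (0.0, 0.0),
                        axis: str = "z") -> RecordingGrid:
    """Evenly spaced planar recording grid at a fixed offset along one axis.

    The default 26 × 47 = 1222 points emulates the transverse recording
    plane used for validation maps; pass smaller ``nx, ny`` for reduced
    density.  ``extent`` is the (width, height) of the plane in μm.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid counts must be >= 1")
    u = origin[0] + (np.linspace(0, extent[0], nx) if nx > 1 else np.array([extent[0] / 2]))
    v = origin[1] + (np.linspace(0, extent[1], ny) if ny > 1 else np.array([extent[1] / 2]))
    uu, vv = np.meshgrid(u, v, indexing="ij")
    flat = np.stack([uu.ravel(), vv.ravel()], axis=1)
    k = "xyz".index(axis)
    points = np.empty((len(flat), 3))
    points[:, k] = plane_offset
    others = [a for a in range(3) if a != k]
    points[:, others[0]] = flat[:, 0]
    points[:, others[1]] = flat[:, 1]
    layout = {"axis": axis, "offset": plane_offset, "nx": nx, "ny": ny,
              "extent": list(extent), "origin": list(origin)}
    return RecordingGrid(points=points, layout=layout)
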