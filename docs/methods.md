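# Methods

This note documents the model, its numerical choices, and the limits of
what the test suite demonstrates.

## Volume conduction as a resistor network

The quasistatic extracellular potential in a purely resistive medium obeys
∇·(σ∇φ) = −I_source.  The admittance method discretizes the tissue volume
into a mesh and compiles it into a network of conductances between mesh
nodes; nodal analysis (Kirchhoff's current law) then gives G v = i, with G
the reduced nodal conductance matrix, i the injected currents, and v the
nodal voltages.  Capacitive elements, anisotropy and electrode-interface
circuits are out of scope: the model is resistive and per-element
isotropic (a per-element scalar resistivity is supported for tetrahedral
meshes; for cubic grids each lattice edge uses the mean resistivity of its
incident voxels).

### Edge conductance rules

* **Cubic grids** — R = ρL/A per lattice edge.  Two cross-section modes:
  * `continuum_A` (default): A = L², i.e. conductance g = σL.  This is the
    standard continuum-equivalent cubic lattice: a lattice of such
    conductors reproduces the 7-point finite-difference Laplacian, and a
    point injection recovers φ = ρI/4πr away from the source with error
    O((L/r)²).  Amplitudes are physical without calibration.
  * `constant_A`: A fixed at 0.25 μm² for every resolution.  All
    conductances, and therefore all voltages, are rescaled by the constant
    factor L²/0.25 relative to `continuum_A` (verified exactly in the
    tests); the `calibrate` operation recovers the physical scale with a
    single least-squares factor.  This mode exists for compatibility with
    the historical compilation convention.
* **Tetrahedra** — the cotangent rule.  For edge AB of one tet, with CD
  the opposite edge and ϑ the interior dihedral angle along CD:
  R_AB = 6ρ·tan(ϑ)/|CD|, equivalently g_AB = σ|CD|cot(ϑ)/6.  Summed over
  the tets sharing an edge this is exactly the off-diagonal entry of the
  piecewise-linear FEM stiffness matrix (asserted against an independent
  gradient-based assembly in the tests).  The dihedral angle is computed
  from the cotangent identity
  cot ϑ = ((u·u)(v·w) − (u·v)(u·w)) / (|u|·|u·(v×w)|) with u along the
  edge that carries the angle and v, w pointing to the two opposite
  vertices.  The absolute value of the triple product makes the result
  orientation-independent; implemented with atan2 so ϑ ∈ (0, π) and
  ϑ = π/2 maps to an exactly open branch (zero conductance).

Degenerate and pathological cases: ϑ → 0 produces very large conductances
(near-shorts) which remain finite in the merged matrix; merged edge
conductances smaller than 1e-9 of the largest are numerical zeros (exact
cancellations of the ideal geometry) and are removed as open branches.
Obtuse dihedral angles give negative conductance contributions; these are
kept in the parallel merge — discarding them would corrupt the stiffness
structure, and the assembled matrix remains positive definite because each
element matrix is — with a warning, or rejected in a strict mode.

### Grounding

After assembly, every hull node (lattice boundary for grids; nodes of
faces belonging to exactly one tet for tet meshes) is tied to a virtual
ground through a resistor equal to the arithmetic mean of the resistances
of its incident edges; edges with non-positive conductance are excluded
from the average since they are not meaningful as wires.  The meshed
volume is the source cloud's axis-aligned bounding box expanded by a
factor 1.42 per side about its centroid, so that sources never sit close
to the grounded hull.

**The grounded hull is a real boundary condition, not an approximation of
infinity.**  Because the per-node ground conductance (≈σL) is comparable
to the local edge conductances, the hull behaves like a Dirichlet surface
displaced outward by roughly one edge length.  For a source at distance a
from the hull this depresses the potential everywhere in the interior by
approximately ρI/(4πa) — a *resolution-independent* offset.  Against the
infinite-medium analytic formula, a centered 1 μA source in a 2 mm
grounded cube therefore shows a ≈27% median discrepancy on the shell
r ∈ [200, 400] μm at every edge length from 80 down to 20 μm; after an
affine fit absorbs the constant offset, the remaining (discretization)
error falls monotonically, 0.47% → 0.11% → 0.015% for L = 80/40/20 μm,
consistent with O(L²) convergence.  Both behaviors are asserted in the
test suite.  Practically: raw admittance-method amplitudes are only
comparable to analytic estimates after amplitude calibration, or with a
bounding volume much larger than the source–recording distances.

### Kuhn grids and hex/tet equivalence

Splitting every voxel of a cubic grid into six tri-rectangular (Kuhn)
tets and compiling with the cotangent rule reproduces the `continuum_A`
grid circuit exactly on every interior lattice edge, and produces no
diagonal resistors at all (diagonal-edge contributions cancel through
ϑ = π/2 terms).  Hull edges differ: a surface edge is incident to 2
voxels instead of 4 (a boundary-line edge to 1), so its cotangent
conductance is half (a quarter) of the grid value.  With identical
Dirichlet conditions on the hull the two compilations are therefore
electrically identical; with the mean-resistance grounding rule the
solved voltages differ by a few percent, concentrated at the hull.

## Solver

Each time step solves G v = i by conjugate gradients with Jacobi
(diagonal) preconditioning, relative residual 1e-9 by default, maximum
10·n iterations, and the previous frame as warm start; the ground
row/column is eliminated rather than pinned with a large conductance, so
the system is SPD and well conditioned.  Units at the solver boundary are
fixed: conductances in S, injections converted nA → A, voltages reported
in mV.  A dense LAPACK solve serves as the independent oracle in tests.

## Source coupling

Source→node assignment is computed once per geometry (it is
time-invariant) and applied to every amplitude column.  "Splitting" uses
trilinear weights over the containing voxel's corners, or barycentric
weights over the containing tet — chosen over inverse-distance weighting
because these are the unique weights consistent with the feedforward
interpolation, exact at nodes, and a partition of unity (so total current
is conserved exactly, which the tests assert to 1e-12).  "Shifting"
assigns each source wholly to the nearest node, ties broken by lowest
node index.  Points on shared faces or lattice planes are resolved
deterministically (lowest tet index; half-open voxel intervals with the
top boundary closed on the last voxel).

Bidirectional coupling is synchronous and staggered: per step, solve the
network from the model's present currents, interpolate the field at each
compartment, apply it as an extracellular potential offset, then advance
the membrane model by dt and carry its new currents into the next frame.
No sub-stepping is attempted.

## Mesh generation

Cubic grids tile the expanded bounding box with voxels of the requested
edge length, extending the lattice outward (centered) when the box side is
not a multiple of it.  Tetrahedral meshes are Delaunay triangulations
(scipy/Qhull) of a body-centered-cubic point lattice: the BCC Delaunay
cell is the tetragonal disphenoid — near-equifacial, dihedral angles 60°
and 90°, no obtuse elements — which is the practical "ideal" tet for
conduction problems, closed at the hull by right-angle tets.  A small
random jitter (5% of the pitch by default; in-plane only on boundary
points so the hull stays flat) breaks the lattice's cospherical
degeneracies so the triangulation is unambiguous; the jitter makes some
dihedrals slightly obtuse, producing small negative merged conductances
that are handled as described above.  The lattice pitch is chosen so the
longest possible edge (a jittered hull-face diagonal) respects the
requested maximum edge length.  Generation is deterministic per seed.
At matched node counts these meshes carry ≈6× more elements per node than
cubic grids (≈5.5 tets per node vs. ≈0.9 voxels per node at ~17k nodes),
which is the complexity ratio the acceptance script reports.

Gmsh MSH (2.2 and 4.1, tet4 only) and TetGen .node/.ele ASCII files are
read and written directly; 1-based external indices are normalized to the
internal 0-based convention on read.

## Synthetic populations

The generator emulates the structure of evoked-potential source data from
laminar tissue: cells on a planar sheet, each a somatic compartment plus a
vertical dendritic cable, with per-cell per-time-step charge balance
enforced exactly (the soma carries the negative of the summed dendritic
currents).  The temporal envelope is a brief biphasic stimulation-artifact
transient (0–2 ms) followed by a biphasic response — a negative
population-spike lobe and a positive after-hyperpolarization lobe
(3–12 ms), built from gamma-like shapes — with per-cell latency jitter and
amplitude gain, optional Gaussian noise on dendritic currents, and a
deterministic seed.  Defaults (16 cells, 400 μm sheet, 300 μm dendrites,
somatic response peak 50 nA, artifact peak 500 nA, dt 0.25 ms, 15 ms
duration) were chosen so analytic LFP peaks at a plane 50 μm below the
sheet fall in the hundreds-of-μV to low-mV range typical of evoked
potentials.  What the generator does *not* emulate: synaptic and channel
kinetics, axonal conduction delays, realistic morphology, correlated
network dynamics, or an electrode model behind the artifact.  Tests that
pass on these populations demonstrate correct field arithmetic and
coupling behavior, not biological fidelity.

The toy compartment model used for coupling tests is a passive linear
cable (membrane capacitance, leak, axial conductances) driven by a
charge-balanced dipolar injection, integrated by forward Euler; it
responds linearly to applied extracellular gradients and is invariant to
spatially uniform offsets, as a membrane model must be.

## Error metrics and calibration

Accuracy is summarized as the time-averaged absolute residual per
recording point, in μV, with μ and σ computed over all points × time
steps.  The amplitude calibration is the single least-squares factor
c = ⟨v_num, v_ana⟩/⟨v_num, v_num⟩; it exactly undoes the constant-A mode's
L²/0.25 rescaling and partially absorbs the grounded-hull offset.

## Known limitations

* Absolute (uncalibrated) accuracy against infinite-medium analytic
  estimates is limited by the grounded hull as analyzed above; this is a
  property of the method's boundary treatment, not of the implementation.
* The analytic oracle is the point-source kernel only; line-source
  kernels for extended compartments are not implemented.
* Obtuse-element behavior of the cotangent rule is kept but not
  theoretically characterized; meshes of the provided generator contain
  only mildly obtuse elements from the degeneracy-breaking jitter.
* Solve-time benchmarking is explicitly not a validation surface; problem
  sizes in tests (up to ~1M nodes in one convergence check, a few
  thousand nodes elsewhere) were chosen as representative desk-scale
  conditions.
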