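# amlfp — admittance-method forward modeling of local field potentials

`amlfp` estimates the extracellular local field potentials (LFPs) generated
by large sets of distributed neuronal current sources, using the admittance
method: the tissue volume is discretized into a mesh, the mesh is compiled
into an equivalent network of resistors, and the nodal voltages produced by
the injected transmembrane currents are solved per time step by sparse
conjugate gradients.  It is aimed at computational neuroscientists who want
a volume-conductor forward model that couples naturally to compartmental
neuron simulations — including bidirectionally, by reading the solved field
back at each compartment — and who want to quantify how mesh geometry
(structured cubic grids vs. unstructured tetrahedra) and source-coupling
strategy (splitting vs. shifting) affect accuracy and cost.

## The model

**Analytic reference.**  In an infinite homogeneous medium of resistivity ρ
the potential of a monopolar point current source is

    φ(r) = ρ I / (4π r)

and many sources superpose.  With ρ in Ω·m, I in nA and r in μm this yields
mV directly.  This estimate (default ρ = 3.8 Ω·m) is the proxy ground truth
against which the numerical solutions are validated.

**Resistor networks.**  Cubic-voxel grids assign each lattice edge the
resistance R = ρL/A.  By default A = L² (the continuum-equivalent cubic
lattice, edge conductance σL), which makes solved amplitudes physical; a
constant-A mode (A = 0.25 μm² at every resolution) is provided for
compatibility with the historical compilation and requires a single
least-squares amplitude calibration.  Tetrahedral meshes use the cotangent
(Duffin) rule: for the edge AB of a tet, with ϑ the dihedral angle along
the opposite edge CD,

    R_AB = 6 ρ tan(ϑ) / |CD|,

and contributions from tets sharing an edge merge as parallel resistors
(1/R_tot = Σ 1/R_k).  Kuhn (tri-rectangular) tetrahedralizations of a cubic
grid compile to exactly the same interior circuit as the grid itself.
Hull nodes are grounded through a resistor equal to the mean of their
incident edge resistances, after the source cloud's bounding box has been
expanded by 142% so sources sit far from the grounded boundary.

**Source coupling.**  Off-node sources are either *split* — distributed to
the corners of the containing element with trilinear (hex) or barycentric
(tet) partition-of-unity weights — or *shifted* wholly to the nearest node.
The same weights interpolate solved voltages back to arbitrary points,
which closes the loop for bidirectional coupling with a compartment model.

## Worked example

Generate a synthetic laminar population (16 charge-balanced cells, artifact
plus population-spike/after-hyperpolarization response), mesh and solve it,
and compare with the analytic estimate on a recording plane 50 μm under the
cells:

```bash
amlfp synth --n-cells 16 --dt 0.5 --seed 42 --out sources.csv
# -> wrote 80 sources × 31 steps to sources.csv
amlfp mesh  --sources sources.csv --geometry hex --edge-length 60 --out mesh.json
# -> hex mesh: 1089 nodes, 800 elements -> mesh.json
amlfp solve --mesh mesh.json --sources sources.csv --out solution.csv
# -> solved 31 steps on 1089 nodes -> solution.csv
amlfp analytic --sources sources.csv --grid grid.csv --out analytic.csv
amlfp compare --numeric numeric.csv --analytic analytic.csv --calibrated --out errors.csv
# -> mu=15.26 μV sigma=38.59 μV -> errors.csv
```

Here `numeric.csv` holds the solved field interpolated at the recording
points (see `amlfp.coupling.interpolate_potential`).  μ and σ are the mean
and standard deviation of the absolute residual against the analytic
estimate over all points and time steps: about 15 μV against signals whose
mean magnitude is ≈495 μV (peak ≈5.2 mV) on this coarse 60 μm mesh.
Without `--calibrated` the residual also contains the constant potential
deficit imposed by the grounded hull of the finite volume (≈175 μV here);
`docs/methods.md` discusses this decomposition.

The geometry × method sensitivity sweep is one command:

```bash
amlfp sweep --config sweep.yaml --out report.csv
```

which tabulates per configuration (hex/tet × split/shift × edge length) the
node and element counts, μ/σ residuals and solver iterations.

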