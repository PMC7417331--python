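"""Source-to-node coupling: splitting, shifting, interpolation, feedback."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amlfp.circuit import Medium, ResistorNetwork, assemble_network, attach_ground
from amlfp.coupling import (
    CurrentSourceSeries,
    assign_sources,
    interpolate_potential,
    run_bidirectional,
    split_weights_hex,
    split_weights_tet,
)
from amlfp.mesh import OutsideMeshError
from amlfp.solver import dense_solve
from amlfp.synth import ToyCompartmentModel


class TestSplitWeights:
    def test_hex_center(self):
        assert np.allclose(split_weights_hex([0.5, 0.5, 0.5]), 0.125)

    def test_hex_corner(self):
        w = split_weights_hex([0.0, 0.0, 0.0])
        assert w[0] == 1.0 and np.allclose(w[1:], 0.0)

    def test_hex_edge_midpoint(self):
        w = split_weights_hex([0.5, 0.0, 0.0])
        assert np.isclose(w[0], 0.5) and np.isclose(w[1], 0.5)
        assert np.allclose(w[2:], 0.0)

    def test_hex_outside_rejected(self):
        with pytest.raises(ValueError):
            split_weights_hex([1.2, 0.0, 0.0])

    @settings(deadline=None, max_examples=100)
    @given(st.tuples(*[st.floats(0, 1) for _ in range(3)]))
    def test_hex_partition_of_unity(self, local):
        w = split_weights_hex(np.array(local))
        assert np.isclose(w.sum(), 1.0, atol=1e-12)
        assert np.all(w >= 0)

    @pytest.mark.parametrize(
        "bary",
        [[0.25, 0.25, 0.25, 0.25], [1, 0, 0, 0], [1 / 3, 1 / 3, 1 / 3, 0]],
    )
    def test_tet_weights_are_barycentric(self, bary):
        assert np.allclose(split_weights_tet(bary), bary)

    def test_tet_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            split_weights_tet([0.5, 0.5, 0.5, 0.5])


class TestAssignSources:
    def _series_at(self, points, amps):
        return CurrentSourceSeries(positions=np.atleast_2d(points),
                                   amplitudes=np.atleast_2d(amps), dt=0.1)

    def test_source_on_node_both_methods(self, small_hex):
        series = self._series_at([50.0, 50.0, 50.0], [[10.0]])
        for method in ("split", "shift"):
            a = assign_sources(small_hex, series, method)
            inj = a.injection_matrix(small_hex.n_nodes) @ series.amplitudes[:, 0]
            node = small_hex.node_index(1, 1, 1)
            assert np.isclose(inj[node], 10.0)
            assert np.isclose(inj.sum(), 10.0)

    def test_voxel_center_split_eight_ways(self, small_hex):
        series = self._series_at([25.0, 25.0, 25.0], [[8.0]])
        a = assign_sources(small_hex, series, "split")
        inj = a.injection_matrix(small_hex.n_nodes) @ series.amplitudes[:, 0]
        assert np.isclose(inj[inj > 0].min(), 1.0)
        assert (inj > 0).sum() == 8

    @pytest.mark.parametrize("method", ["split", "shift"])
    def test_total_current_conserved(self, small_hex, small_tet, method):
        rng = np.random.default_rng(2)
        for mesh in (small_hex, small_tet):
            pos = rng.uniform(5, 95, size=(20, 3))
            amps = rng.normal(size=(20, 7))
            series = self._series_at(pos, amps)
            a = assign_sources(mesh, series, method)
            inj = a.injection_matrix(mesh.n_nodes) @ series.amplitudes
            assert np.allclose(inj.sum(axis=0), amps.sum(axis=0), atol=1e-12)

    def test_split_equals_shift_on_nodes(self, small_hex):
        pos = small_hex.node_positions()[[3, 10, 17]]
        series = self._series_at(pos, np.eye(3))
        i_split = assign_sources(small_hex, series, "split").injection_matrix(
            small_hex.n_nodes) @ series.amplitudes
        i_shift = assign_sources(small_hex, series, "shift").injection_matrix(
            small_hex.n_nodes) @ series.amplitudes
        assert np.allclose(i_split, i_shift, atol=1e-12)

    def test_outside_sources_listed(self, small_hex):
        series = self._series_at([[50, 50, 50], [500, 0, 0], [0, 500, 0]],
                                 np.ones((3, 1)))
        with pytest.raises(OutsideMeshError, match=r"\[1, 2\]"):
            assign_sources(small_hex, series, "split")


class TestInterpolatePotential:
    def test_uniform_field(self, small_hex, small_tet):
        for mesh in (small_hex, small_tet):
            v = np.full(mesh.n_nodes, 3.7)
            assert np.isclose(interpolate_potential(mesh, v, [33.0, 41.0, 55.0]), 3.7)

    def test_voxel_center_single_hot_corner(self, small_hex):
        v = np.zeros(small_hex.n_nodes)
        v[small_hex.node_index(0, 0, 0)] = 8.0
        assert np.isclose(interpolate_potential(small_hex, v, [25.0, 25.0, 25.0]), 1.0)

    def test_exact_at_nodes(self, small_tet):
        rng = np.random.default_rng(0)
        v = rng.normal(size=small_tet.n_nodes)
        for k in (0, 5, 11):
            assert np.isclose(
                interpolate_potential(small_tet, v, small_tet.nodes[k]), v[k]
            )

    def test_affine_field_exact(self, small_hex, small_tet):
        a, b = np.array([0.3, -1.2, 0.7]), 4.2
        for mesh in (small_hex, small_tet):
            v = mesh.node_positions() @ a + b
            rng = np.random.default_rng(1)
            for p in rng.uniform(10, 90, size=(20, 3)):
                assert np.isclose(interpolate_potential(mesh, v, p), p @ a + b)

    def test_matrix_voltages(self, small_hex):
        v = np.tile(np.arange(small_hex.n_nodes, dtype=float)[:, None], (1, 3))
        out = interpolate_potential(small_hex, v, [50.0, 50.0, 50.0])
        assert out.shape == (3,)
        assert np.allclose(out, out[0])


class _FrozenModel:
    """Emits fixed currents; ignores field feedback entirely."""

    def __init__(self, positions, currents):
        self._pos = np.asarray(positions, float)
        self._cur = np.asarray(currents, float)

    def positions(self):
        return self._pos

    def currents(self):
        return self._cur

    def apply_extracellular(self, v):
        pass

    def step(self, dt):
        pass


class TestRunBidirectional:
    def test_zero_currents_zero_field(self, tiny_pipeline):
        _, _, mesh, net = tiny_pipeline
        pos = np.array([[100.0, 100, 50], [100, 100, 150]])
        model = _FrozenModel(pos, [0.0, 0.0])
        sol, trace = run_bidirectional(net, mesh, model, n_steps=3, dt=0.1)
        assert np.allclose(sol.voltages, 0.0)
        assert np.allclose(trace, 0.0)

    def test_feedback_free_model_matches_feedforward(self, tiny_pipeline):
        from amlfp.coupling import assign_sources
        from amlfp.solver import solve_series

        _, _, mesh, net = tiny_pipeline
        pos = np.array([[100.0, 100, 50], [100, 100, 150]])
        cur = np.array([2.0, -2.0])
        model = _FrozenModel(pos, cur)
        sol, _ = run_bidirectional(net, mesh, model, n_steps=3, dt=0.1,
                                   tolerance=1e-12)
        series = CurrentSourceSeries(positions=pos,
                                     amplitudes=np.tile(cur[:, None], (1, 3)), dt=0.1)
        ref = solve_series(net, assign_sources(mesh, series, "split"), series,
                           tolerance=1e-12)
        assert np.allclose(sol.voltages, ref.voltages, rtol=1e-8, atol=1e-12)

    def test_nonfinite_currents_abort_with_step(self, tiny_pipeline):
        _, _, mesh, net = tiny_pipeline

        class Exploding(_FrozenModel):
            def __init__(self, pos):
                super().__init__(pos, [0.0, 0.0])
                self.n = 0

            def currents(self):
                return np.array([np.nan, 0.0]) if self.n >= 2 else self._cur

            def step(self, dt):
                self.n += 1

        with pytest.raises(Exception, match="step 2"):
            run_bidirectional(net, mesh,
                              Exploding(np.array([[100.0, 100, 50], [100, 100, 150]])),
                              n_steps=5, dt=0.1)

    def test_two_compartment_toy_matches_hand_stepped_reference(self, tiny_pipeline):
        """Three coupled steps reproduce an explicit hand integration."""
        _, _, mesh, net = tiny_pipeline
        pos = np.array([[100.0, 100.0, 50.0], [100.0, 100.0, 150.0]])
        cm, gl, ga = 0.01, 0.001, 0.05

        def drive(t):
            return np.array([1.0, -1.0]) * np.sin(2 * np.pi * t / 5.0)

        model = ToyCompartmentModel(pos, cm=cm, gl=gl, ga=ga, drive=drive)
        dt, n_steps = 0.1, 3
        sol, trace = run_bidirectional(net, mesh, model, n_steps=n_steps, dt=dt,
                                       tolerance=1e-12)

        # --- independent hand-stepped reference (dense solve, explicit Euler)
        from amlfp.coupling import assign_sources

        probe = CurrentSourceSeries(positions=pos, amplitudes=np.zeros((2, 1)), dt=dt)
        P = assign_sources(mesh, probe, "split").injection_matrix(net.n_nodes)
        vm = np.zeros(2)
        ve = np.zeros(2)
        t = 0.0
        for step in range(n_steps):
            vi = vm + ve
            axial = ga * (vi[0] - vi[1])
            i_mem = np.array([-axial, axial]) + drive(t)
            assert np.allclose(trace[:, step], i_mem, atol=1e-12)
            v_nodes = dense_solve(net, P @ i_mem)
            assert np.allclose(sol.voltages[:, step], v_nodes, rtol=1e-7, atol=1e-12)
            # the freshly solved field is applied before the membrane step
            ve = np.array([interpolate_potential(mesh, v_nodes, p) for p in pos])
            vi_new = vm + ve
            axial_new = ga * (vi_new[0] - vi_new[1])
            dvm = (np.array([-axial_new, axial_new]) + drive(t) - gl * vm) / cm
            vm = vm + dt * dvm
            t += dt
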