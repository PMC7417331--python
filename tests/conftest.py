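import numpy as np
import pytest

from amlfp import (
    BoundingBox,
    Medium,
    PopulationSpec,
    assemble_network,
    attach_ground,
    build_hex_mesh,
    generate_population,
    generate_tet_mesh,
    make_recording_grid,
    scaled_bounding_box,
)


@pytest.fixture
def unit_box():
    return BoundingBox([0.0, 0.0, 0.0], [100.0, 100.0, 100.0])


@pytest.fixture
def small_hex(unit_box):
    """3×3×3-node cubic grid, 50 μm voxels."""
    return build_hex_mesh(unit_box, 50.0)


@pytest.fixture
def small_tet(unit_box):
    return generate_tet_mesh(unit_box, 80.0, seed=7)


@pytest.fixture
def regular_tet():
    """Regular tetrahedron with unit edge length (μm coordinates)."""
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
        ]
    )


@pytest.fixture
def trirect_tet():
    """Tri-rectangular tet: three mutually orthogonal unit edges at A."""
    return np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]])


@pytest.fixture
def tiny_population():
    return generate_population(
        PopulationSpec(n_cells=4, n_compartments=3, dt=1.0, duration=15.0, seed=11)
    )


@pytest.fixture
def tiny_pipeline(tiny_population):
    """Population + covering hex mesh + grounded network + recording grid."""
    grid = make_recording_grid(plane_offset=-50.0, nx=4, ny=4, extent=(400.0, 400.0))
    cloud = np.concatenate([tiny_population.positions, grid.points])
    box = scaled_bounding_box(cloud, 1.42)
    mesh = build_hex_mesh(box, 100.0)
    network = attach_ground(assemble_network(mesh, Medium(3.8)))
    return tiny_population, grid, mesh, network
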