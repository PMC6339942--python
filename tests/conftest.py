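import numpy as np
import pytest

from flutterpath import (
    build_adjacency,
    build_tensor_field,
    generate_annulus,
    generate_planar_sheet,
    substrate_preset,
)


@pytest.fixture(scope="session")
def clinical_cfg():
    """Homogeneous CV 650 mm/s, constant ERP 250 ms, isotropic."""
    return substrate_preset("clinical_example")


@pytest.fixture(scope="session")
def small_sheet():
    return generate_planar_sheet(20.0, 20.0, 1.0)


@pytest.fixture(scope="session")
def small_sheet_adj(small_sheet):
    return build_adjacency(small_sheet)


@pytest.fixture(scope="session")
def bench_annulus():
    """Annulus whose inner-rim circuit sustains at ERP 250 ms / CV 650 mm/s."""
    return generate_annulus(35.0, 5.0, 2.0)


@pytest.fixture(scope="session")
def bench_annulus_adj(bench_annulus):
    return build_adjacency(bench_annulus)


@pytest.fixture(scope="session")
def bench_annulus_tf(bench_annulus, clinical_cfg):
    return build_tensor_field(bench_annulus, clinical_cfg)


@pytest.fixture()
def two_triangle_square():
    """Smallest manifold patch: a unit square split along one diagonal."""
    from flutterpath import TriangularSurfaceMesh

    nodes = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]
    )
    triangles = np.array([[0, 1, 2], [0, 2, 3]])
    mesh = TriangularSurfaceMesh(nodes=nodes, triangles=triangles)
    mesh.validate()
    return mesh
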