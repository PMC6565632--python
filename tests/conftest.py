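"""Shared fixtures: small tube meshes and Womersley cases."""

import numpy as np
import pytest

from hemowss import GeneratorSpec, SurfaceMesh, WomersleyCase, WssSeries, make_tube


@pytest.fixture(scope="session")
def tube():
    """Aorta-scale tube: R = 16 mm, L = 100 mm."""
    return make_tube(radius=16.0, length=100.0, axial_res=11, circ_res=12)


@pytest.fixture(scope="session")
def single_node_mesh():
    """Degenerate one-triangle patch for per-node indicator tests.

    The tangent plane is z = 0; the outward normal is +z, so tangent WSS
    vectors live in the x-y plane.
    """
    nodes = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    tris = np.array([[0, 1, 2]])
    normals = np.tile([0.0, 0.0, 1.0], (3, 1))
    return SurfaceMesh(nodes, tris, normals)


@pytest.fixture(scope="session")
def moderate_case():
    """Mixed 3-harmonic forcing at Womersley number α₁ ≈ 3, where the
    start-up transient decays within a few cycles."""
    return WomersleyCase(
        radius=0.002,
        period=0.8,
        pressure_gradient={
            0: 40.0,
            1: 120.0 * np.exp(-0.5j),
            2: 50.0 * np.exp(0.8j),
            3: 25.0,
        },
    )


def series_at_single_node(times, vectors, period=0.8, n_extra_nodes=0):
    """Build a WssSeries holding the given per-sample vectors at node 0.

    Extra nodes (if any) replicate node 0, which keeps shape handling
    honest without changing per-node values.
    """
    vectors = np.asarray(vectors, dtype=float)
    wss = np.repeat(vectors[:, None, :], 1 + n_extra_nodes, axis=1)
    return WssSeries(np.asarray(times, dtype=float), period, wss)
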