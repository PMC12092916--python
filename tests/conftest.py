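"""Shared fixtures: meshes and trees are generated once per session."""

import numpy as np
import pytest

from lotcrt import (AnatomyParams, ConductionModel, FiberField, TreeParams,
                    assign_fibers, build_idealized_biventricular_mesh,
                    build_slab_mesh, calibrate_fascicle_cv,
                    generate_his_purkinje)


@pytest.fixture(scope="session")
def small_params():
    # coarse anatomy for unit tests; the acceptance suite uses the defaults
    return AnatomyParams(edge_length=2.5, seed=3)


@pytest.fixture(scope="session")
def small_mesh(small_params):
    return build_idealized_biventricular_mesh(small_params)


@pytest.fixture(scope="session")
def small_fibers(small_mesh):
    return assign_fibers(small_mesh)


@pytest.fixture(scope="session")
def small_tree(small_mesh):
    return generate_his_purkinje(small_mesh, TreeParams(seed=3))


@pytest.fixture(scope="session")
def small_model(small_tree):
    return calibrate_fascicle_cv(small_tree, ConductionModel())


@pytest.fixture(scope="session")
def slab():
    """30 x 12 x 8 mm slab at 1 mm resolution, fibers along +x."""
    mesh = build_slab_mesh(30.0, 12.0, 8.0, 1.0)
    fibers = FiberField.uniform(mesh, (1.0, 0.0, 0.0))
    return mesh, fibers


def corner_source(mesh):
    return int(np.argmin(np.linalg.norm(mesh.vertices, axis=1)))
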