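import numpy as np
import pytest

from epicosim import field as fd
from epicosim import geometry as geo
from epicosim import snn as sn


@pytest.fixture(scope="session")
def small_mesh():
    return geo.generate_synthetic_hippocampus(12, 9, curvature=0.15, seed=0)


@pytest.fixture(scope="session")
def small_setup():
    """Mesh + cloud + relabeled assignment, the standard small fixture."""
    mesh = geo.generate_synthetic_hippocampus(12, 9, curvature=0.15, seed=0)
    cloud = geo.generate_neuron_cloud(mesh, 300, thickness=0.5, seed=1)
    assignment = geo.assign_neurons_to_vertices(mesh, cloud)
    mesh = geo.relabel_vertices(mesh, assignment)
    assignment = geo.assign_neurons_to_vertices(mesh, cloud)
    return mesh, cloud, assignment


@pytest.fixture(scope="session")
def single_node_seizure():
    """One uncoupled epileptogenic node (x0 = -1.6), onset-initialized,
    simulated through a full seizure plus return to rest."""
    conn = fd.SparseConnectome.empty(1)
    kernel = fd.LocalKernel.empty(1)
    params = fd.SEMParameters(x0=-1.6)
    return fd.run_field(1, conn, kernel, params, [0], duration=6000.0)


@pytest.fixture
def tiny_cloud():
    rng = np.random.default_rng(5)
    n = 40
    return geo.NeuronCloud(
        positions=rng.uniform(0, 5, size=(n, 3)),
        apd_coords=rng.uniform(0, 5, size=(n, 2)),
        neuron_ids=np.arange(n),
    )


@pytest.fixture
def isolated_net(tiny_cloud):
    return sn.build_synthetic_connectivity(tiny_cloud, mean_degree=0, seed=0)
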