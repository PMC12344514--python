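import numpy as np
import pytest

from connsim import connectivity as cn
from connsim import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, 4 networks of 5 ROIs, short scans; shared across tests."""
    return sd.make_cohort(
        n_subjects=20,
        network_sizes=(5, 5, 5, 5),
        heterogeneity=0.2,
        T=600,
        censor_fraction=0.1,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort_network_items(small_cohort):
    """Censored scans -> full edge vectors -> network matrices, once."""
    cohort = small_cohort
    edge_vectors = {}
    network_mats = {}
    for sid in cohort.subject_ids:
        censored = cn.censor_and_concatenate([cohort.scans[sid]], 0.10)
        ev = cn.correlation_edges(censored)
        edge_vectors[sid] = ev
        network_mats[sid] = cn.network_matrix(ev, cohort.parcellation)
    return edge_vectors, network_mats
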