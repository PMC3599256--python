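"""Shared fixtures: the default log table and kernel pipeline are built
once per session (the LP/interp fits and the schedule are deterministic,
so sharing them is safe)."""

import numpy as np
import pytest

from plfpipe import dfg, synth
from plfpipe.plf_kernel import default_log_table


@pytest.fixture(scope="session")
def log_table():
    return default_log_table()


@pytest.fixture(scope="session")
def kernel_graph(log_table):
    return dfg.build_kernel_dfg(table=log_table)


@pytest.fixture(scope="session")
def kernel_schedule(kernel_graph):
    return synth.asap_schedule(kernel_graph, synth.compute_dii(10, 4))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_partials(rng, n_sites, normalised=True):
    vals = rng.uniform(0.0, 1.0, (n_sites, 4))
    if normalised:
        vals[np.arange(n_sites), rng.integers(0, 4, n_sites)] = 1.0
    return vals


def random_stochastic_matrix(rng):
    return rng.dirichlet(np.ones(4), size=4)
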