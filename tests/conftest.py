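"""Shared fixtures: small networks and cheap rasters.

Heavy case-example simulations used by the acceptance tests are session-
scoped so several criteria can share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import rivalsim as rs


@pytest.fixture(scope="session")
def single_neuron():
    """One unconnected excitatory neuron."""
    layout = rs.PopulationLayout(
        n_total=1,
        syn_class=np.array([0], dtype=np.int8),
        pool=np.array([-1], dtype=np.int8),
    )
    return rs.Connectivity(
        layout=layout,
        pre=np.empty(0, dtype=np.int64),
        post=np.empty(0, dtype=np.int64),
        weight=np.empty(0),
        kind="unstructured",
        params={},
    )


@pytest.fixture(scope="session")
def tiny_discrete():
    """Small discrete mutual-inhibition network for fast dynamical tests."""
    return rs.build_discrete_mutual_inhibition(n=400, k=20, seed=7)


@pytest.fixture(scope="session")
def case_discrete():
    """Case-example discrete network (full size)."""
    return rs.build_discrete_mutual_inhibition(seed=11)
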