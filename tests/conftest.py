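import numpy as np
import pytest

from hlanet import (
    BipartiteNetwork,
    build_network,
    fast_greedy_modules,
    generate_network,
    benchmark_small,
    unit_preset,
)
from hlanet.records import BindingRecord


def records_from_pairs(pairs):
    """[(hla, peptide, is_positive)] -> BindingRecord list."""
    return [
        BindingRecord(hla=h, peptide=p, label="positive" if pos else "negative")
        for h, p, pos in pairs
    ]


def network_from_edges(edge_dict):
    """{(hla, peptide): weight in {1,2}} -> BipartiteNetwork."""
    hlas = sorted({h for h, _ in edge_dict})
    peps = sorted({p for _, p in edge_dict})
    W = np.zeros((len(hlas), len(peps)))
    for (h, p), w in edge_dict.items():
        W[hlas.index(h), peps.index(p)] = w
    return BipartiteNetwork(hlas, peps, W)


@pytest.fixture(scope="session")
def bench_spec():
    return benchmark_small(seed=1)


@pytest.fixture(scope="session")
def bench_data(bench_spec):
    return generate_network(bench_spec)


@pytest.fixture(scope="session")
def bench_network(bench_data):
    records, _ = bench_data
    return build_network(records)


@pytest.fixture(scope="session")
def bench_partition(bench_network):
    return fast_greedy_modules(bench_network)


@pytest.fixture(scope="session")
def unit_network():
    records, _ = generate_network(unit_preset(seed=3))
    return build_network(records)
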