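"""Shared fixtures: deterministic toy graphs and the planted benchmark.

The expensive SIR ground truth for the benchmark is computed once per
session at the benchmark's standard conditions (beta = 1.5 x epidemic
threshold, gamma = 1, 100 repetitions, master seed 0).
"""

import pytest

import ocrank as oc


@pytest.fixture(scope="session")
def toys():
    return oc.toy_fixtures()


@pytest.fixture(scope="session")
def benchmark():
    """(graph, planted membership sets) of the default planted fixture."""
    return oc.planted_benchmark()


@pytest.fixture(scope="session")
def benchmark_params(benchmark):
    g, _ = benchmark
    beta = 1.5 * oc.epidemic_threshold(g)
    return oc.SIRParams(beta=beta, gamma=1.0, reps=100, seed=0)


@pytest.fixture(scope="session")
def benchmark_influence(benchmark, benchmark_params):
    g, _ = benchmark
    return oc.influence_ranking(g, benchmark_params)
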