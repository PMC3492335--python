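"""Shared fixtures: synthetic datasets at several scales.

Everything is generated in memory from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import triomics as t
from triomics.simulate import simulate_dataset, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    return t.SimulationConfig(
        seed=11,
        n_chromosomes=4,
        genes_per_chromosome=30,
        tiles_per_chromosome=8,
        planted=(
            t.PlantedSet("gain+over", 5, 8),
            t.PlantedSet("hyper+under", 5, 8),
        ),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_genome):
    return simulate_dataset(small_config, small_genome)


@pytest.fixture(scope="session")
def small_calls(small_dataset, small_genome):
    d = small_dataset
    return t.build_call_matrix(
        d.segments, d.beta, d.expression, small_genome.annotation,
        d.meth_probe_map, d.expr_probe_map,
    )


@pytest.fixture(scope="session")
def recovery_config():
    """Full-scale planted-recovery conditions: 19 cases, 22 autosomes."""
    return t.SimulationConfig(
        seed=7,
        planted=(
            t.PlantedSet("gain+over", 10, 8),
            t.PlantedSet("hyper+under", 10, 8),
            t.PlantedSet("hypo+over", 5, 7),
            t.PlantedSet("loss+under", 5, 7),
        ),
    )


@pytest.fixture(scope="session")
def recovery_run(recovery_config):
    genome = simulate_genome(recovery_config)
    data = simulate_dataset(recovery_config, genome)
    calls = t.build_call_matrix(
        data.segments, data.beta, data.expression, genome.annotation,
        data.meth_probe_map, data.expr_probe_map,
    )
    return genome, data, calls


def make_call_matrix(genes, samples, assignments) -> t.CallMatrix:
    """Construct a CallMatrix from {(gene, sample): [channels]} entries."""
    calls = t.CallMatrix(list(genes), list(samples))
    for (g, s), channels in assignments.items():
        gi = calls.genes.get_loc(g)
        si = calls.samples.get_loc(s)
        for ch in channels:
            calls.values[gi, si, t.CHANNELS.index(ch)] = True
    return calls
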