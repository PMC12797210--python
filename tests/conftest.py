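"""Shared fixtures: seeded generators and random simulation instances."""

from __future__ import annotations

import numpy as np
import pytest

from evosim import LengthDistribution, IndelParams, SimConfig
from evosim.cli_io import random_tree

MASTER_SEED = 20240917


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture
def zipf_default() -> LengthDistribution:
    """The benchmark-regime length distribution: Zipf a=2, truncated at 50."""
    return LengthDistribution("zipf", 2.0, 50)


@pytest.fixture
def default_params(zipf_default) -> IndelParams:
    """Benchmark-regime rates: insertion 0.03, deletion 0.09 per site."""
    return IndelParams(0.03, 0.09, zipf_default)


def random_instance(rng: np.random.Generator, max_leaves: int = 10):
    """One random (tree, config) pair for the engine-equivalence sweeps.

    Root lengths up to 200 and small trees with realistic branch lengths,
    so each instance carries a handful of indel events.
    """
    n_leaves = int(rng.integers(2, max_leaves + 1))
    mean_branch = float(rng.uniform(0.01, 0.15))
    tree = random_tree(n_leaves, mean_branch, rng)
    config = SimConfig(
        root_length=int(rng.integers(10, 201)),
        insertion_rate=float(rng.uniform(0.0, 0.08)),
        deletion_rate=float(rng.uniform(0.0, 0.12)),
        model="none",
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return tree, config


def random_event_stream(rng: np.random.Generator, n0: int, params: IndelParams,
                        branch_length: float = 0.3):
    """Convenience wrapper drawing one branch's Gillespie stream."""
    from evosim.evo_model import simulate_branch_events

    return simulate_branch_events(n0, branch_length, params, rng)
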