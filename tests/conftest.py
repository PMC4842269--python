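"""Shared fixtures: one default simulated dataset and one full pipeline run.

The simulation and the end-to-end run are expensive relative to any single
assertion, so they are session-scoped and shared by all tests that inspect
the default scenario.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tssmapper.pipeline import PipelineConfig, run_core
from tssmapper.simulate import SimConfig, make_training_labels, simulate_dataset

warnings.filterwarnings("ignore", message="only .* examples in the rarest class")


@pytest.fixture(scope="session")
def sim_default():
    """The default simulation scenario (100 kb, 100 TSSs per condition)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def training_labels(sim_default):
    return make_training_labels(sim_default)


@pytest.fixture(scope="session")
def core_result(sim_default, training_labels):
    """Full pipeline run (peaks -> SVM -> merge -> categorize -> filter ->
    promoters -> protein DB) on the default scenario."""
    return run_core(sim_default.replicon, sim_default.genes, sim_default.operons,
                    sim_default.tracks, training_labels, PipelineConfig(seed=1))


def match_any(position: int, strand: str, truth: list[tuple[int, str]],
              max_dist: int = 2) -> bool:
    """Does (position, strand) fall within max_dist of any truth site?"""
    return any(s == strand and abs(p - position) <= max_dist for p, s in truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
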