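"""Shared fixtures: small synthetic scenarios and toy structures.

Fixtures are generated programmatically — no binary data on disk.  The
"small" scenario is a scaled-down stated world used by unit tests to keep
runtimes low; acceptance tests construct the full default scenario
themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from epishift.ensemble import align_ensemble, ca_mask, combine_trajectories, coordinate_pca
from epishift.structure_io import AtomRecord
from epishift.synthetic import ConformerScenario, make_toy_topology, simulate_model_set


@pytest.fixture(scope="session")
def small_scenario() -> ConformerScenario:
    """Scaled-down conformer world: 1 repeat, 60 frames, same planted deltas."""
    return ConformerScenario(n_frames=60, n_repeats=1,
                             transition_midpoint=(("WT", 20.0), ("VARIANT", 30.0)),
                             state_gap=20.0, midpoint_jitter=4.0, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(small_scenario):
    """Aligned two-model ensemble with PCA and planted state labels."""
    trajs, truths = simulate_model_set(small_scenario)
    ens = combine_trajectories(trajs)
    mask = ca_mask(ens.topology)
    ens = align_ensemble(ens, mask)
    pca = coordinate_pca(ens, mask)
    states = [s for tr in truths for s in tr.state_labels]
    return ens, pca, states, truths


@pytest.fixture(scope="session")
def toy_topology():
    return make_toy_topology(12)


@pytest.fixture
def three_atoms() -> list[AtomRecord]:
    return [
        AtomRecord(1, "CA", "C", 1, "GLY", "A", 1.7),
        AtomRecord(2, "CA", "C", 2, "GLY", "A", 1.7),
        AtomRecord(3, "CA", "C", 3, "GLY", "A", 1.7),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
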