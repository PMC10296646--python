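"""Shared fixtures: synthetic study datasets at the design's desk scale.

The heavy fixtures are session-scoped: one textured 8-sample/3-microscope/
2-scan dataset (64x64 tiles, 12 layers, 1% counting noise, broadband offsets
up to +/-20%) used for calibration/bootstrap checks, and one marker-scene
dataset (32x32 tiles) used for the unmixing scenario checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from mifcal import (
    RunConfig,
    SimulationConfig,
    TruthModel,
    gauge_fix_truth,
    microscope_library,
    run_full_calibration,
    simulate_dataset,
)

TEXTURE_SEED = 1
MARKERS_SEED = 2


@pytest.fixture(scope="session")
def texture_sim():
    config = SimulationConfig()
    truth = TruthModel.random(config, seed=TEXTURE_SEED)
    dataset = simulate_dataset(config, truth)
    return config, truth, dataset


@pytest.fixture(scope="session")
def texture_report(texture_sim):
    _, _, dataset = texture_sim
    return run_full_calibration(dataset)


@pytest.fixture(scope="session")
def texture_gauge_truth(texture_sim):
    config, truth, dataset = texture_sim
    return gauge_fix_truth(truth, config, dataset.scenes)


@pytest.fixture(scope="session")
def markers_sim():
    config = SimulationConfig(height=32, width=32, scene="markers", hpfs_per_scan=2)
    truth = TruthModel.random(config, seed=MARKERS_SEED)
    dataset = simulate_dataset(config, truth)
    libraries = {
        mid: microscope_library(truth, config, m, mid)
        for m, mid in enumerate(dataset.microscope_ids)
    }
    return config, truth, dataset, libraries


@pytest.fixture(scope="session")
def markers_report(markers_sim):
    _, _, dataset, libraries = markers_sim
    reference = dataset.microscope_ids[1]
    return run_full_calibration(
        dataset, RunConfig(reference_microscope=reference), libraries=libraries
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
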