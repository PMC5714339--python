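"""Shared fixtures: one simulated study reused across test modules."""

import numpy as np
import pytest

from footcall.pipeline import analyze_peaks
from footcall.synth import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One study-conditions simulation (protection factor 4, CV 10%,
    5% dropout, five replicates)."""
    cfg = SimulationConfig(seed=11)
    sequence, truth, records, fragments = simulate_study(cfg)
    return cfg, sequence, truth, records, fragments


@pytest.fixture(scope="session")
def analysis(study):
    cfg, _seq, _truth, records, fragments = study
    return analyze_peaks(records, fragments, cfg.region_length)


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = SimulationConfig(replicate_cv=0.0, dropout_p=0.0, size_jitter_sd=0.0, seed=3)
    sequence, truth, records, fragments = simulate_study(cfg)
    return cfg, sequence, truth, records, fragments


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
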