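"""Shared fixtures: generator configs, small fixture datasets, and the
session-scoped default benchmark (built once, reused by the pipeline-level
and acceptance tests)."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

import carospec as cs
from carospec.pipeline import run_pipeline

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("carospec").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gen_cfg() -> cs.GeneratorConfig:
    return cs.GeneratorConfig()


@pytest.fixture(scope="session")
def quiet_cfg() -> cs.GeneratorConfig:
    """No baseline, no noise, no spikes: pure fingerprint signal."""
    return cs.GeneratorConfig().quiet()


@pytest.fixture(scope="session")
def small_standards(gen_cfg) -> cs.LabeledSpectraSet:
    return cs.simulate_standards_dataset((4, 4, 4), gen_cfg, seed=11)


@pytest.fixture(scope="session")
def characteristic_peaks() -> cs.PeakSet:
    """The two shared carotenoid bands, as the triage stage consumes them."""
    return cs.PeakSet(
        centers=np.array([1160.0, 1517.0]),
        scores=np.array([4.0, 3.9]),
        k=2,
        match_tolerance=5.0,
    )


@pytest.fixture(scope="session")
def benchmark() -> cs.Benchmark:
    """The default synthetic benchmark (7 lines x 4 maps + 34 standards)."""
    return cs.simulate_benchmark(seed=1)


@pytest.fixture(scope="session")
def pipeline_untrained(benchmark):
    """Full pipeline up to dataset assembly (no model training)."""
    return run_pipeline(benchmark, seed=1, train=False)
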