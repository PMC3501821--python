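"""Shared fixtures: synthetic datasets and a cached benchmark evaluation."""

from __future__ import annotations

import numpy as np
import pytest

from spikeface.config import PipelineConfig
from spikeface.pipeline import run_evaluate
from spikeface.synth import make_dataset


@pytest.fixture(scope="session")
def benchmark_dataset(tmp_path_factory):
    """Default 5-class benchmark: 20 images per class, frontal lighting."""
    root = tmp_path_factory.mktemp("faces")
    manifest = make_dataset(root, n_per_class=20, seed=11)
    return root, manifest


@pytest.fixture(scope="session")
def benchmark_eval(benchmark_dataset):
    """One full 70/30 train/evaluate run with the default configuration."""
    root, _ = benchmark_dataset
    return run_evaluate(root, PipelineConfig(), split_seed=0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small 3-class dataset for fast pipeline plumbing tests."""
    root = tmp_path_factory.mktemp("faces_small")
    manifest = make_dataset(
        root, n_per_class=4, classes=("happy", "sad", "surprise"), seed=5
    )
    return root, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
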