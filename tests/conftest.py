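"""Shared fixtures: synthetic datasets and one session-scoped fitted hierarchy."""

from __future__ import annotations

import pytest

from medhier.config import RunConfig
from medhier.model import TopicHierarchyModel
from medhier.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset_main():
    """Two-level corpus (3 categories x 3 leaves, 70 records each) with 50
    paraphrased queries at substitution rate 0.5."""
    cfg = GeneratorConfig(
        branching=(3, 3), docs_per_leaf=70, seed_examples_per_category=30,
        n_queries=50, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def run_config_main():
    return RunConfig(k_max=6, seed=11)


@pytest.fixture(scope="session")
def fitted_main(dataset_main, run_config_main):
    model = TopicHierarchyModel(
        dataset_main.corpus, dataset_main.prior, dataset_main.lexicon,
        dataset_main.tagger, run_config_main,
    )
    return model.fit()


@pytest.fixture(scope="session")
def dataset_tiny():
    """Small single-level corpus for fast unit-level checks."""
    cfg = GeneratorConfig(
        branching=(3,), docs_per_leaf=40, seed_examples_per_category=15,
        n_queries=5, seed=5,
    )
    return generate_dataset(cfg)
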