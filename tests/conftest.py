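"""Shared fixtures: the packaged corpus, pipeline runs, and a seeded random
BEL term generator used by the round-trip tests."""

import random

import pytest

from belex import core
from belex.fixtures import (
    WORKED_SENTENCES,
    dictionary_entries,
    gene_go_associations,
    go_parents,
    gold_entity_entries,
    gold_statements,
    standoff_mentions,
)
from belex.lexicon import LexiconIndex
from belex.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def sentences():
    return dict(WORKED_SENTENCES)


@pytest.fixture(scope="session")
def dict_index():
    return LexiconIndex(dictionary_entries())


@pytest.fixture(scope="session")
def gold_records():
    return gold_statements()


@pytest.fixture(scope="session")
def worked_results(dict_index):
    """Phase-1 pipeline results on the worked corpus (corrected mode, run1)."""
    return run_pipeline(
        WORKED_SENTENCES, dict_index, standoff_mentions(), None,
        gene_go_associations(), go_parents(), PipelineConfig(),
    )


@pytest.fixture(scope="session")
def phase2_results(dict_index):
    return run_pipeline(
        WORKED_SENTENCES, dict_index, standoff_mentions(), gold_entity_entries(),
        gene_go_associations(), go_parents(), PipelineConfig(phase="phase2_gold"),
    )


@pytest.fixture
def rng():
    return random.Random(20240915)
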