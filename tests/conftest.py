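"""Shared fixtures: small reference models and clean simulated datasets."""

import numpy as np
import pytest

from pseudoscan import build_reference_model, evolve_along_tree


SMALL_MODEL_KW = dict(
    n_exons=6,
    exon_length_range=(60, 150),
    intron_length_range=(120, 300),
)


@pytest.fixture(scope="session")
def small_model():
    """Compact 6-exon gene for fast unit tests."""
    return build_reference_model(**SMALL_MODEL_KW, seed=11)


@pytest.fixture(scope="session")
def full_model():
    """ENaC-like 12-exon gene (exons numbered 2..13, condensed introns)."""
    return build_reference_model(n_exons=12, seed=7)


@pytest.fixture(scope="session")
def quartet_tree():
    return "((A:1,B:1):0.5,(C:1,D:1):0.5);"


@pytest.fixture(scope="session")
def clean_quartet(full_model, quartet_tree):
    """Zero-rate loci: every tip identical to the reference assembly."""
    loci, truth = evolve_along_tree(full_model, quartet_tree, 0.0, 0.0, [], seed=5)
    return loci, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
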