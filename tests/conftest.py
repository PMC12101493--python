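"""Shared fixtures: one default synthetic ocean, preprocessed and clustered."""

import numpy as np
import pandas as pd
import pytest

from eigenlipid.network import adjacency, compute_eigenlipids, detect_modules, tom_similarity
from eigenlipid.preprocess import preprocess
from eigenlipid.synthetic import OceanConfig, generate_dataset

#: the default study conditions: 5 modules × 60 lipids, 40 unassigned,
#: 90 reference-region samples, log-scale noise 0.15
DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def dataset():
    cfg = OceanConfig(seed=DEFAULT_SEED)
    metadata, features, blanks, truth = generate_dataset(cfg)
    return cfg, metadata, features, blanks, truth


@pytest.fixture(scope="session")
def clr_full(dataset):
    _, _, features, blanks, _ = dataset
    clr, report = preprocess(features, blanks)
    return clr, report


@pytest.fixture(scope="session")
def reference(dataset, clr_full):
    """CLR view of the reference (Atlantic) region plus detected modules."""
    _, metadata, _, _, truth = dataset
    clr, _ = clr_full
    ref_samples = metadata.index[metadata["region"] == "atlantic"]
    clr_ref = clr.subset_samples(ref_samples)
    net = adjacency(clr_ref, beta=6)
    tom = tom_similarity(net)
    detected = detect_modules(tom, min_module_size=10)
    elset = compute_eigenlipids(clr_ref, detected.labels)
    return clr_ref, elset


@pytest.fixture(scope="session")
def species_map(dataset):
    from eigenlipid.lipids import parse_annotation_table

    _, _, features, _, _ = dataset
    return parse_annotation_table(features.annotations)
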