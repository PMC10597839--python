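from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from clonoverge import (
    SimulationConfig,
    assemble_cells,
    call_clonotypes,
    group_tcr_types,
    make_fixture_germline,
    merge_samples,
    read_cell_labels,
    read_contig_annotations,
    simulate_study,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def germline():
    return make_fixture_germline(1)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Default-config study simulation (50 clones + one 5-variant spike,
    4+4 mice, ~2,000 cells), seeded."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_study(SimulationConfig(seed=7), out)


@pytest.fixture(scope="session")
def pipeline_result(study_bundle):
    """The bundle re-read from disk and pushed through the pipeline."""
    collections = [
        read_contig_annotations(study_bundle.contig_csv(s), s)
        for s in study_bundle.sample_ids
    ]
    labels = read_cell_labels(study_bundle.labels_path)
    merged, label_map = merge_samples(collections, labels)
    cells = assemble_cells(merged)
    clonotypes = call_clonotypes(cells)
    types = group_tcr_types(clonotypes)
    return {
        "records": merged,
        "labels": label_map,
        "cells": cells,
        "clonotypes": clonotypes,
        "types": types,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)
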