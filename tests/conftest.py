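"""Shared fixtures: a small simulated dataset and its pipeline products."""

from __future__ import annotations

import pytest

from smallrna import annotation, preprocessing
from smallrna.synthetic_data import SimulationConfig, simulate_libraries


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=1,
        n_hairpins=20,
        n_transcripts=40,
        n_ncrna_refs=12,
        library_depths=(40_000, 40_000),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smallsim")
    return simulate_libraries(small_config, outdir)


@pytest.fixture(scope="session")
def small_clean(small_dataset):
    """(tags, counts1, counts2) from cleaning both small-sim libraries."""
    tags1, c1 = preprocessing.clean_reads(small_dataset.fastq[0], library=1)
    tags2, c2 = preprocessing.clean_reads(small_dataset.fastq[1], library=2)
    tags = preprocessing.merge_tag_counts(tags1, tags2)
    return tags, c1, c2


@pytest.fixture(scope="session")
def small_annotated(small_dataset, small_clean):
    tags, _, _ = small_clean
    ncrna_ref = annotation.load_class_reference(small_dataset.ncrna_reference)
    mature_ref = annotation.load_mature_reference(small_dataset.mature_reference)
    return annotation.annotate_tags(tags, ncrna_ref, mature_ref)
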