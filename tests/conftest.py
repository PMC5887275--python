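import pytest

from dsearch.corpus_io import DatasetRecord
from dsearch.experiments import (run_planted_linear_ltr,
                                 run_reformulation_experiment)
from dsearch.index_core import build_index
from dsearch.synthdata import GeneratorConfig, generate


@pytest.fixture
def tiny_records():
    """Five hand-written dataset descriptions over two repositories."""
    return [
        DatasetRecord("d1", "gene expression profiling", "geo",
                      "expression data for tp53 gene in human cells",
                      "gene expression omnibus repository"),
        DatasetRecord("d2", "protein sequencing", "pride",
                      "mass spectrometry proteomics of cell lines"),
        DatasetRecord("d3", "apoptosis pathway assay", "geo",
                      "gene regulation during apoptosis and cell death",
                      "gene expression omnibus repository"),
        DatasetRecord("d4", "mouse brain imaging", "geo",
                      "mri volumes of m musculus brain development"),
        DatasetRecord("d5", "cancer genomics cohort", "pride",
                      "somatic mutations in tumor and normal tissue samples"),
    ]


@pytest.fixture
def tiny_index(tiny_records):
    return build_index(tiny_records)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_bundle(default_config):
    return generate(default_config)


@pytest.fixture(scope="session")
def default_index(default_bundle):
    return build_index(default_bundle.records)


@pytest.fixture(scope="session")
def small_bundle():
    """A 60-document task small enough for exhaustive oracles."""
    return generate(GeneratorConfig(
        n_docs=60, n_queries=5, grade2_per_topic=3, grade1_per_topic=2,
        judged_irrelevant_per_query=5, seed=11,
    ))


@pytest.fixture(scope="session")
def small_index(small_bundle):
    return build_index(small_bundle.records)


@pytest.fixture(scope="session")
def reformulation_outcome(default_config, default_bundle, default_index):
    return run_reformulation_experiment(default_config, bundle=default_bundle,
                                        index=default_index)


@pytest.fixture(scope="session")
def ltr_outcome():
    return run_planted_linear_ltr(n_queries=20, docs_per_query=30, seed=7)
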