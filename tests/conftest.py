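import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pathocode.corpus_io import EntityMention, Report
from pathocode.synthetic import (
    GeneratorConfig,
    NoiseConfig,
    generate_reports,
    generate_terminologies,
)

warnings.filterwarnings("ignore", message="labels absent")


@pytest.fixture
def annotated_report() -> Report:
    """Hand-built report: one sentence per entity type."""
    text = "Specimen received: biopsy of thyroid. The test performed was immunohistochemistry. Findings are consistent with osteosarcoma."
    report = Report(
        report_id="R-fixture",
        text=text,
        language="en",
        sentences=[(0, 37), (38, 82), (83, 125)],
        entities=[
            EntityMention(19, 36, "SAMPLE_TYPE", "biopsy of thyroid",
                          {"SNOMEDCT": "12345678"}),
            EntityMention(61, 81, "TEST_PERFORMED", "immunohistochemistry",
                          {"LOINC": "1234-5"}),
            EntityMention(112, 124, "FINDING", "osteosarcoma",
                          {"SNOMEDCT": "87654321", "ICD11": "2B51.0"}),
        ],
    )
    report.validate()
    return report


@pytest.fixture(scope="session")
def small_corpus():
    """Small clean synthetic corpus plus its terminology tables."""
    cfg = GeneratorConfig(
        n_reports=60, n_concepts=8, seed=11, noise=NoiseConfig.none()
    )
    tables = generate_terminologies(cfg)
    reports = generate_reports(cfg, tables)
    return cfg, tables, reports
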