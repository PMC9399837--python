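import pytest
from hypothesis import HealthCheck, settings

from fusiontriage.annotation import load_annotation
from fusiontriage.report import build_report
from fusiontriage.simulate import (
    build_gene_structures,
    build_reference_cohort,
    write_reference_cohort,
)
from fusiontriage.triage import TriageConfig, classify_cohort

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """All reference-cohort files written to a session temp directory."""
    return write_reference_cohort(tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def annotation(fixture_paths):
    return load_annotation(fixture_paths["gtf"], fixture_paths["domains"])


@pytest.fixture(scope="session")
def structures():
    return build_gene_structures()


@pytest.fixture(scope="session")
def cohort():
    return build_reference_cohort()


@pytest.fixture(scope="session")
def cfg():
    return TriageConfig()


@pytest.fixture(scope="session")
def results(cohort, annotation, cfg):
    return classify_cohort(cohort.samples, cohort.calls, annotation, cohort.db, cfg)


@pytest.fixture(scope="session")
def report(results, cohort):
    return build_report(results, cohort.samples, cohort.db)
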