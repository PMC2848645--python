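import pytest

from motorsnp import annotate_variant, load_domain_model, load_snp_catalog, summarize_study


@pytest.fixture(scope="session")
def model():
    return load_domain_model()


@pytest.fixture(scope="session")
def catalog():
    return load_snp_catalog()


@pytest.fixture(scope="session")
def annotated(catalog, model):
    return [
        annotate_variant(e.record, e.mapped(), model, reference_anomaly=e.reference_anomaly)
        for e in catalog
    ]


@pytest.fixture(scope="session")
def summary(annotated, model):
    return summarize_study(annotated, model)
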