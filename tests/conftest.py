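import pytest

from geosift import CleaningPolicy, SeriesRecord, clean_text


@pytest.fixture
def default_policy():
    return CleaningPolicy()


@pytest.fixture
def freq_policy():
    """Policy used for the frequency-based backends: stop words removed."""
    return CleaningPolicy(remove_stopwords=True)


def make_doc(accession, text, policy=None):
    """Clean a raw text under a (default) policy; test helper."""
    return clean_text(text, policy or CleaningPolicy(), accession=accession)


def make_series(accession, title="t", summary="", overall_design="",
                species="Homo sapiens",
                experiment_types=("expression profiling by array",),
                platform_vendor="Affymetrix", retired=False,
                is_subseries=False, condition_labels=()):
    return SeriesRecord(
        accession=accession, title=title, summary=summary,
        overall_design=overall_design, species=species,
        experiment_types=frozenset(experiment_types),
        platform_vendor=platform_vendor, retired=retired,
        is_subseries=is_subseries, condition_labels=frozenset(condition_labels),
    )
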