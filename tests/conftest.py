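import pytest

from adrtriage.classify import get_backend
from adrtriage.corpus import MeaningUnit, SectionLabel
from adrtriage.lexsearch import LexiconEntry, Query
from adrtriage.simulate import GeneratorConfig, generate_corpus, make_query_for_corpus


def make_mu(text: str, mu_id: str = "d0:0:0", section: SectionLabel = SectionLabel.ABSTRACT) -> MeaningUnit:
    doc_id = mu_id.split(":")[0]
    return MeaningUnit(
        mu_id=mu_id,
        doc_id=doc_id,
        section_label=section,
        section_position=0,
        char_start=0,
        char_end=len(text),
        text=text,
        word_count=len(text.split()),
    )


@pytest.fixture(scope="session")
def query():
    return Query(
        main_drug=LexiconEntry(
            canonical="pembrolizumab", synonyms=["rivaroxaban", "cisplatin", "platinol"]
        )
    )


@pytest.fixture(scope="session")
def backend(query):
    return get_backend("baseline", query=query)


@pytest.fixture(scope="session")
def small_gold():
    """Small seeded synthetic corpus with hits and all distractor types."""
    return generate_corpus(GeneratorConfig(
        n_docs=30, sections_per_doc=4, sentences_per_section=(4, 8),
        hit_rate=0.02, nonserious_rate=0.03, negated_rate=0.02,
        generic_ae_rate=0.03, serious_no_drug_rate=0.03, seed=11,
    ))


@pytest.fixture(scope="session")
def small_gold_query(small_gold):
    return make_query_for_corpus(small_gold)
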