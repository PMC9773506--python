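import pytest

from adrtriage.classify import SeriousnessLabel, default_serious_terms, get_backend
from adrtriage.decision import (
    DecisionEngine,
    PipelineConfig,
    Stage,
    match_generic_ae,
    match_generic_serious,
    process_unit,
    rank_documents,
    rescue_serious,
)
from adrtriage.simulate import generate_corpus, GeneratorConfig, make_query_for_corpus
from conftest import make_mu


class TestGenericAeRegex:
    @pytest.mark.parametrize("text, expected", [
        ("Grade 3 TRAEs were common.", True),
        ("serious adverse events occurred", True),
        ("Several side effects were noted.", True),
        ("Caesarean section", False),          # no boundary, acronyms case-sensitive
        ("the aes were mild", False),          # lowercase acronym does not count
        ("No complications were seen.", False),
    ])
    def test_generic_ae_families(self, text, expected):
        assert match_generic_ae(text)[0] is expected


class TestGenericSeriousRegex:
    @pytest.mark.parametrize("text, expected", [
        ("Two SAEs were reported.", True),
        ("grade 4/5 reactions occurred in 3 patients", True),
        ("grade 5 toxicities were observed", True),
        ("serious adverse reactions were seen", True),
        ("grade 2 reactions", False),
        ("sae in lowercase is ignored", False),
    ])
    def test_serious_families(self, text, expected):
        assert match_generic_serious(text)[0] is expected


class TestRescue:
    def test_always_serious_terms_match_with_category(self):
        terms = default_serious_terms()
        matches = rescue_serious("patient developed ventricular fibrillation", terms)
        assert matches and matches[0].outcome_category == "life-threatening"

    def test_synonym_of_serious_term_matches(self):
        matches = rescue_serious(
            "community-acquired pneumonia was diagnosed", default_serious_terms())
        assert any(m.term_id == "pneumonia" for m in matches)

    def test_benign_text_yields_no_rescue(self):
        assert rescue_serious("patient recovered fully", default_serious_terms()) == []


PEMBRO = "There was one treatment-related death due to myositis in the pembrolizumab group."
RIVA = "We observed Rivaroxaban-induced rash in 60% of the patients"


class TestProcessUnit:
    def test_serious_related_event_is_a_hit(self, query, backend):
        unit = process_unit(make_mu(PEMBRO), query, backend)
        assert unit.is_hit and unit.hit_score == 1.0
        assert unit.stage_reached is Stage.SERIOUSNESS

    def test_non_serious_adr_reaches_seriousness_but_is_not_a_hit(self, query, backend):
        unit = process_unit(make_mu(RIVA), query, backend)
        assert unit.stage_reached is Stage.SERIOUSNESS
        assert not unit.is_hit
        assert unit.seriousness.label is SeriousnessLabel.IMPORTANT_MEDICAL_EVENT

    def test_unit_without_query_drug_stops_at_the_gate(self, query, backend):
        unit = process_unit(make_mu("Two SAEs were reported in this study."), query, backend)
        assert unit.stage_reached is Stage.DRUG_GATE
        assert not unit.is_hit and unit.drug_matches == []

    def test_hit_invariant_holds_structurally(self, query, backend):
        unit = process_unit(make_mu(PEMBRO), query, backend)
        assert unit.drug_matches
        assert unit.relationship.score >= 0.2 or unit.regex_ae
        assert any(e.entity_type.value == "AE" for e in unit.entities)
        serious = (unit.seriousness.label is SeriousnessLabel.SERIOUS
                   or unit.regex_serious or unit.rescue_serious_terms)
        assert serious

    def test_rescue_only_path_is_a_hit(self, query):
        # a backend blind to seriousness rejects the unit; the always-serious
        # rescue list applied by the engine still makes it a hit
        blind = get_backend("baseline", query=query,
                            serious_outcome_cues=[], serious_terms=[])
        text = ("Pembrolizumab-associated ventricular fibrillation was recorded in "
                "one elderly patient during infusion.")
        unit = process_unit(make_mu(text), query, blind,
                            serious_terms=default_serious_terms())
        assert unit.seriousness.label is not SeriousnessLabel.SERIOUS
        assert unit.rescue_serious_terms
        assert unit.is_hit

    def test_disabling_rescue_removes_exactly_the_rescue_hits(self, query):
        blind = get_backend("baseline", query=query,
                            serious_outcome_cues=[], serious_terms=[])
        text = ("Pembrolizumab-associated ventricular fibrillation was recorded in "
                "one elderly patient during infusion.")
        with_rescue = process_unit(make_mu(text), query, blind,
                                   serious_terms=default_serious_terms())
        without = process_unit(
            make_mu(text), query, blind,
            config=PipelineConfig(use_serious_rescue=False),
            serious_terms=default_serious_terms(),
        )
        assert with_rescue.is_hit and with_rescue.rescue_serious_terms
        assert not without.is_hit


class TestProcessCorpus:
    def test_funnel_monotone_and_aligned_recovery(self, small_gold, small_gold_query):
        backend = get_backend("baseline", query=small_gold_query)
        engine = DecisionEngine(small_gold_query, backend)
        results, funnel = engine.process_corpus(small_gold.tables)
        for prev, cur in zip(funnel.stages, funnel.stages[1:]):
            assert cur.n_docs <= prev.n_docs and cur.n_mu <= prev.n_mu
        predicted_hits = {u.mu.mu_id for r in results for u in r.hits}
        gold_hits = {g.mu_id for g in small_gold.gold_units if g.is_hit_gold}
        assert predicted_hits == gold_hits
        for r in results:
            assert r.kept == bool(r.hits)

    def test_corpus_without_drug_mentions_keeps_nothing(self, query, backend):
        gold = generate_corpus(GeneratorConfig(
            n_docs=5, hit_rate=0.0, nonserious_rate=0.0, negated_rate=0.0,
            generic_ae_rate=0.0, serious_no_drug_rate=0.0, seed=3,
        ))
        engine = DecisionEngine(query, backend)
        results, funnel = engine.process_corpus(gold.tables)
        assert all(not r.kept for r in results)
        assert funnel.stages[-1].n_mu == 0

    def test_disabling_generic_ae_regex_never_increases_hits(self, small_gold, small_gold_query):
        backend = get_backend("baseline", query=small_gold_query)
        on = DecisionEngine(small_gold_query, backend)
        off = DecisionEngine(small_gold_query, backend,
                             PipelineConfig(use_generic_ae_regex=False))
        hits_on = {u.mu.mu_id for r in on.process_corpus(small_gold.tables)[0] for u in r.hits}
        hits_off = {u.mu.mu_id for r in off.process_corpus(small_gold.tables)[0] for u in r.hits}
        assert hits_off <= hits_on


class TestRanking:
    def _result(self, doc_id, scores):
        from adrtriage.decision import AnnotatedUnit, DocumentResult, rank_score

        hits = []
        for i, s in enumerate(scores):
            unit = AnnotatedUnit(mu=make_mu("x y z", mu_id=f"{doc_id}:0:{i}"),
                                 is_hit=True, hit_score=s)
            hits.append(unit)
        cfg = PipelineConfig()
        return DocumentResult(doc_id=doc_id, hits=hits, kept=bool(hits),
                              rank_score=rank_score(hits, cfg))

    def test_documents_without_hits_are_filtered_out(self):
        a = self._result("A", [1.0])
        b = self._result("B", [])
        ranked = rank_documents([a, b])
        assert [r.doc_id for r in ranked] == ["A"]

    def test_more_hits_rank_first_at_equal_max_score(self):
        three = self._result("three", [1.0, 1.0, 1.0])
        one = self._result("one", [1.0])
        ranked = rank_documents([one, three])
        assert [r.doc_id for r in ranked] == ["three", "one"]
        # score formula: max + 0.1 * log2(1 + n)
        assert three.rank_score == pytest.approx(1.0 + 0.1 * 2.0)
        assert one.rank_score == pytest.approx(1.0 + 0.1 * 1.0)

    def test_ties_break_on_doc_id_for_reproducibility(self):
        x = self._result("doc-b", [1.0])
        y = self._result("doc-a", [1.0])
        assert [r.doc_id for r in rank_documents([x, y])] == ["doc-a", "doc-b"]
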