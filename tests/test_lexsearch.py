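import random
import string

import pytest

from adrtriage.corpus import ContentSection, CorpusTables, Document, SectionLabel
from adrtriage.lexsearch import (
    LexiconEntry,
    Query,
    expand_indication,
    expressions_for_entry,
    find_exact,
    find_fuzzy,
    load_query,
    load_serious_terms,
    tag_document_indications,
)
from oracles import (
    closed_form_expansion_count,
    enumerate_expansions,
    naive_exact_scan,
    regex_fuzzy_present,
)

QUERY_TSV = """role\tcanonical\tsynonym\toutcome_category
main_drug\tDEBIO 1143\tAT-406\t
main_drug\tDEBIO 1143\tSM-406\t
main_drug\tDEBIO 1143\tXevinapant\t
second_drug\tCisplatin\tPlatinol\t
indication\tSquamous cell carcinoma of head and neck\t\t
"""


class TestLexiconLoading:
    def test_query_with_synonym_expansion(self, tmp_path):
        path = tmp_path / "query.tsv"
        path.write_text(QUERY_TSV, encoding="utf-8")
        query = load_query(path)
        assert query.main_drug.canonical == "DEBIO 1143"
        assert len(query.main_drug.surfaces) >= 4
        assert "xevinapant" in query.main_drug.surfaces
        assert query.second_drug.canonical == "Cisplatin"
        assert [i.canonical for i in query.indications] == [
            "Squamous cell carcinoma of head and neck"
        ]

    def test_empty_synonym_column_keeps_canonical_only(self, tmp_path):
        path = tmp_path / "query.tsv"
        path.write_text("role\tcanonical\tsynonym\nmain_drug\taspirin\t\n", encoding="utf-8")
        query = load_query(path)
        assert query.main_drug.surfaces == ["aspirin"]

    def test_duplicate_synonyms_are_deduplicated(self, tmp_path):
        base = tmp_path / "a.tsv"
        duped = tmp_path / "b.tsv"
        base.write_text(QUERY_TSV, encoding="utf-8")
        duped.write_text(QUERY_TSV + "main_drug\tDEBIO 1143\tat-406\t\n", encoding="utf-8")
        assert load_query(base) == load_query(duped)

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("canonical\tsynonym\nx\ty\n", encoding="utf-8")
        with pytest.raises(ValueError, match="missing columns"):
            load_query(path)

    def test_serious_terms_carry_outcome_category(self, tmp_path):
        path = tmp_path / "serious.tsv"
        path.write_text(
            "role\tcanonical\tsynonym\toutcome_category\n"
            "serious_term\tventricular fibrillation\t\tlife-threatening\n",
            encoding="utf-8",
        )
        terms = load_serious_terms(path)
        assert terms[0].outcome_category == "life-threatening"


class TestFindExact:
    def test_hyphen_is_a_word_boundary(self):
        matches = find_exact({"cisplatin"}, "Cisplatin-based chemotherapy was given.")
        assert [(m.char_start, m.char_end) for m in matches] == [(0, 9)]

    def test_no_match_inside_a_longer_word(self):
        assert find_exact({"AE"}, "CAESAR trial results") == []

    def test_overlapping_terms_all_reported(self):
        matches = find_exact({"platinol", "cisplatin"}, "platinol (cisplatin)")
        assert sorted(m.term_id for m in matches) == ["cisplatin", "platinol"]

    def test_agrees_with_naive_scan_on_random_texts(self):
        rng = random.Random(42)
        words = ["".join(rng.choices(string.ascii_lowercase, k=rng.randint(2, 8)))
                 for _ in range(120)]
        terms = sorted(set(rng.sample(words, 50)))
        for _ in range(1000):
            text_words = rng.choices(words, k=rng.randint(3, 25))
            glue = rng.choice([" ", "  ", "-", ", ", ". "])
            text = glue.join(w.upper() if rng.random() < 0.2 else w for w in text_words)
            got = sorted((m.char_start, m.char_end, m.term_id)
                         for m in find_exact(terms, text))
            want = naive_exact_scan(terms, text)
            assert got == want, (terms, text)


class TestExpandIndication:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_count_matches_closed_form_and_brute_force(self, n):
        tokens = [f"tok{i}" for i in range(n)]
        exprs = expand_indication(" ".join(tokens))
        assert len(exprs) == closed_form_expansion_count(n)
        assert {e.tokens for e in exprs} == enumerate_expansions(tokens)

    def test_three_token_root_has_twelve_expressions(self):
        assert len(expand_indication("alpha beta gamma")) == 12

    def test_permuted_and_truncated_forms_of_a_real_indication(self):
        exprs = {e.tokens for e in expand_indication("B-cell chronic lymphocytic leukaemia")}
        assert ("b-cell", "lymphocytic", "leukaemia") in exprs
        assert ("lymphocytic", "leukaemia", "b-cell") in exprs

    def test_stop_tokens_removed_before_expansion(self):
        exprs = expand_indication("carcinoma of the head")
        assert all("of" not in e.tokens and "the" not in e.tokens for e in exprs)

    def test_single_token_root_returned_exact(self):
        exprs = expand_indication("pneumonia")
        assert len(exprs) == 1 and exprs[0].tokens == ("pneumonia",)

    def test_long_roots_capped_to_large_subsets(self):
        tokens = [f"t{i}" for i in range(7)]
        exprs = expand_indication(" ".join(tokens))
        assert all(len(e.tokens) >= 5 for e in exprs)
        want = {p for p in enumerate_expansions(tokens, min_size=5)}
        assert {e.tokens for e in exprs} == want


class TestFindFuzzy:
    def test_bounded_gap_accepts_inserted_tokens(self):
        exprs = expand_indication("B-cell lymphocytic leukaemia")
        matches = find_fuzzy(exprs, "B-cell and C-cell lymphocytic leukaemia")
        assert matches and matches[0].kind == "fuzzy"

    def test_exact_root_matches_with_full_span(self):
        text = "Relapsed B-cell lymphocytic leukaemia was studied."
        root = "B-cell lymphocytic leukaemia"
        exprs = expand_indication(root)
        spans = {(m.char_start, m.char_end) for m in find_fuzzy(exprs, text)}
        start = text.index("B-cell")
        assert (start, start + len(root)) in spans

    def test_gap_above_twenty_characters_rejected(self):
        exprs = [e for e in expand_indication("B-cell lymphocytic leukaemia")
                 if len(e.tokens) == 3]
        filler = "x" * 25
        assert find_fuzzy(exprs, f"B-cell {filler} lymphocytic {filler} leukaemia") == []

    def test_agrees_with_regex_oracle_on_random_plantings(self):
        rng = random.Random(7)
        vocab = ["alpha", "beta", "gamma", "delta", "omega"]
        fillers = ["and", "of", "zz", "qqqqqqqq", "x" * 12, "y" * 22]
        for _ in range(1000):
            tokens = tuple(rng.sample(vocab, rng.randint(2, 3)))
            expr = [e for e in expand_indication(" ".join(tokens))
                    if e.tokens == tokens]
            text = " ".join(rng.choices(vocab + fillers, k=rng.randint(2, 8)))
            got = bool(find_fuzzy(expr, text))
            want = regex_fuzzy_present(tokens, text)
            assert got == want, (tokens, text)


class TestDocumentIndicationTagging:
    def _doc(self, doc_id, section_texts):
        secs = [ContentSection(doc_id=doc_id, section_label=SectionLabel.ABSTRACT,
                               position=i, text=t)
                for i, t in enumerate(section_texts)]
        return Document(doc_id=doc_id, sections=secs)

    def _query(self):
        return Query(
            main_drug=LexiconEntry(canonical="xevinapant"),
            indications=[LexiconEntry(canonical="Squamous cell carcinoma of head and neck")],
        )

    def test_document_mentioning_indication_is_tagged(self):
        tables = CorpusTables(documents=[self._doc(
            "a", ["Patients had squamous cell carcinoma of head and neck at baseline."])])
        tags = tag_document_indications(tables, self._query())
        assert tags["a"] == {"Squamous cell carcinoma of head and neck"}

    def test_document_without_indication_tokens_untagged(self):
        tables = CorpusTables(documents=[self._doc("b", ["No relevant disease terms appear here."])])
        assert tag_document_indications(tables, self._query())["b"] == set()

    def test_tokens_split_across_sections_do_not_combine(self):
        tables = CorpusTables(documents=[self._doc(
            "c", ["The squamous carcinoma cohort was large.", "Lesions of the neck and head."])])
        # each section alone lacks a full expression of >= 2 matching tokens
        query = Query(
            main_drug=LexiconEntry(canonical="xevinapant"),
            indications=[LexiconEntry(canonical="squamous neck")],
        )
        assert tag_document_indications(tables, query)["c"] == set()
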