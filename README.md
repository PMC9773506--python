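# adrtriage

Literature triage for **serious adverse drug reactions (ADRs)**.

Regulators and pharmacovigilance teams must monitor the biomedical
literature for sentences that state an *established* relationship between a
monitored drug and a *serious* adverse event — one that, per the regulatory
definition, results in death, is life-threatening, requires or prolongs
hospitalisation, causes persistent disability, or is a congenital anomaly.
Such sentences are extremely rare (on the order of 0.2% of sentences in a
drug-centred literature pull), which makes exhaustive manual review
impractical. `adrtriage` implements the screening pipeline for this task:
it turns documents into sentence-level *meaning units*, finds the ones that
mention a monitored drug, decides which of those state a serious
drug-related event ("hits"), ranks the documents that contain hits, and
evaluates the whole chain against gold labels.

## The decision diagram

Every meaning unit passes through a fixed conjunction of filters:

1. **Drug gate** — exact, case-insensitive, word-boundary dictionary match
   of the query drug and all its synonyms (Aho–Corasick multi-pattern
   search). Units without a monitored drug go no further.
2. **Generic regex rules** — unit-level regular expressions for
   non-specific AE mentions (`adverse event(s)`, `TRAEs`, …) and for
   non-specific *serious* mentions (`SAE(s)`, `grade 4/5 reactions`, …),
   run on every drug-containing unit.
3. **Relationship** — a binary classifier scores whether the unit states a
   drug–event causality relationship; the unit passes when the score
   reaches the positivity threshold (default 0.2) or a generic AE regex
   fired.
4. **Entities** — named-entity recognition (gated at score ≥ 0.5) must
   yield at least one DRUG span and one AE evidence; a generic AE regex hit
   counts as AE evidence with `source="regex"`.
5. **Seriousness** — a three-way classifier (`serious` /
   `important_medical_event` / `none`); a unit counts as serious when the
   label is `serious`, a generic serious regex fired, or — for units the
   classifier rejected — an *always-serious* term (e.g. "ventricular
   fibrillation", "intracranial bleeding") is recovered by fuzzy matching.

A unit passing all five stages is a **hit**. Documents with at least one
hit are kept and ranked by

```
rank = w1 · max(hit_score) + w2 · log2(1 + n_hits)        (w1=1.0, w2=0.1)
```

Indication terms ("squamous cell carcinoma of head and neck") are tagged at
document level only, using a permutation fuzzy matcher: a root term is
expanded into every ordered permutation of every token subset of size ≥ 2,
and an expression matches when its tokens occur in order with at most 20
characters between consecutive tokens.

The classification stage is a pluggable backend. The shipped backend is a
deterministic rule/lexicon system (cue phrases, negation guards, outcome
vocabularies — all plain-text config files), which makes the full pipeline
exactly testable offline; a transformer backend satisfying the same
three-task contract can be registered for production use, with fine-tuning
metadata provided by `make_finetune_config()`.

## Worked example

Generate a synthetic gold-labelled corpus (50 documents, 1% planted hits),
run the pipeline with the aligned query, and score it:

```bash
adrtriage simulate --n-docs 50 --hit-rate 0.01 --seed 3 --out demo/sim
adrtriage run --corpus demo/sim/corpus.jsonl --query demo/sim/query.tsv --out demo/run
adrtriage evaluate --gold demo/sim/gold_units.jsonl \
    --gold-docs demo/sim/gold_docs.jsonl --pred demo/run --out demo/metrics
adrtriage report --funnel demo/run/funnel.json
```

which prints

```
{"documents_kept": 8, "hits": 9, "out": "demo/run"}
{"document_precision": 1.0, "f1": 1.0, ..., "precision": 1.0, "recall": 1.0}
stage               N_docs      N_mu
collected               50       874
drug_gate               26        29
relationship            23        25
entities                23        25
serious_hit              8         9
```

Reading the funnel: of 874 meaning units in 50 documents, 29 mention a
query drug, 25 of those state a causal relationship with the required
entities, and 9 carry serious evidence — the planted hits, recovered with
precision = recall = 1.0 because the generator, the query lexicon and the
rule-based backend share the same vocabularies. The ranked document list
(`demo/run/documents.jsonl`) puts the two-hit document first
(`SYN00015`, rank score 1.158 = 1.0 + 0.1·log₂3) ahead of one-hit
documents (score 1.1).

## Layout

| module | role |
|---|---|
| `adrtriage.corpus` | three-table document model; JSONL fixture and PubMed efetch XML readers |
| `adrtriage.preprocess` | biomedical sentence splitting; short-sentence merge rule |
| `adrtriage.lexsearch` | lexicon TSVs, Aho–Corasick exact search, permutation fuzzy matcher |
| `adrtriage.classify` | three-task backend contract, rule-based baseline, fine-tune metadata |
| `adrtriage.decision` | decision diagram, rescue rules, ranking, funnel statistics |
| `adrtriage.evaluate` | sentence / per-section / document metrics |
| `adrtriage.simulate` | deterministic synthetic corpus generator with gold labels |
| `adrtriage.cli` | `ingest` / `simulate` / `run` / `evaluate` / `report` subcommands |

See `docs/methods.md` for the modelling choices, parameters and known
limitations.
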