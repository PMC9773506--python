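# Methods

## Problem and unit of analysis

The package screens drug-centred literature for sentences stating an
established link between a monitored drug and a serious adverse event.
The unit of analysis is the *meaning unit*: a sentence, possibly
concatenated with a short neighbour. Working at sentence scale keeps
units within the input budget of transformer classifiers and, more
importantly, matches how reviewers cite evidence; working below document
scale is what makes the extreme class imbalance (roughly 2 relevant units
per 1,000) tractable with a cheap lexical gate in front of the expensive
stages.

## Corpus model

A corpus is three tables — documents, contents (one row per section),
meaning units — with referential integrity enforced after every load.
Section labels form a closed vocabulary (TITLE, ABSTRACT, INTRO, METHODS,
RESULTS, DISCUSS, CASE, CONCL, OTHER); free-text headers map onto it via
an alias table, defaulting to OTHER, because section headers in the wild
are uncontrolled. Character offsets are 0-based, half-open, in Unicode
code points, always relative to the parent section text; a meaning unit
therefore records its parent section's position as well as its label.
The PubMed XML reader collects the title and the labelled abstract parts
(one section per part) and deliberately ignores tables, figures, captions
and reference lists — boilerplate-heavy regions that add noise without
adding reviewable sentences. Multi-paragraph abstracts yield one section
per labelled part.

## Sentence splitting and the merge rule

Splitting is rule-based: a break candidate is terminal punctuation
followed by whitespace, vetoed when the preceding token is in a
protected-abbreviation list (`i.v.`, `e.g.`, `Fig.`, `vs.`, …; a
plain-text config file) or is a single-letter initial. Decimal numbers
never split because the candidate requires whitespace after the period.
This trades recall on exotic boundary cases for exact reproducibility and
zero model dependencies.

Very short sentences rarely carry a complete drug–event statement; the
missing half usually sits next door. A sentence of at most `short_max`
(10) words is therefore merged with a neighbour: preferentially the
previous unit, while that unit's accumulated word count is below
`neighbor_max` (20); otherwise the next sentence, when it has fewer than
20 words. The pass is a single left-to-right sweep; each short sentence
merges at most once and merges never cascade, so the output is a
deterministic partition of the sentence sequence. Sentences below
`short_min` (4) words — fragments and headings — are treated as short for
the same reason. Words are whitespace-delimited tokens. The thresholds
are configuration, not tuned values.

## Lexical search

Drug names have essentially invariant spelling, so drug search is exact:
an Aho–Corasick automaton over all normalized (case-folded,
whitespace-collapsed) surface forms of the query drug and its synonyms,
with matches accepted only on word boundaries (a boundary is the text
edge or any non-alphanumeric character, so hyphenated compounds like
"cisplatin-based" still match "cisplatin"). Matching is case-insensitive
throughout because casing in titles and abstracts varies. The automaton
is hand-implemented and verified in the test suite against a naive
scan-and-filter oracle on randomized corpora.

Indication terms are multi-token and surface permuted or truncated. A
root term is tokenized (stop tokens *of, the, and, in* removed) and
expanded into **all** ordered permutations of all token subsets of size
≥ 2, deduplicated — a deterministic superset of any random-suppression
expansion scheme, chosen for reproducibility. The count follows the
closed form Σ_{k≥2} C(n,k)·k! (2, 12, 60, 320 for n = 2…5); roots longer
than `max_expand_tokens` (5) tokens enumerate only subsets of size
≥ n − 2 to bound the output. An expression matches when its tokens occur
in order, each on word boundaries, with at most `max_gap` (20) characters
between the end of one token and the start of the next (endpoints
exclusive of the tokens). Overlapping matches of one root collapse to the
longest span. Indication tagging is per-section and document-level only;
it asserts mention, not relationship.

## Classification backends

The three tasks (relationship, NER, seriousness) are independent — none
consumes another's output — which keeps the decision logic free to
combine them. The backend contract is three pure functions of the unit
text. The shipped rule-based backend:

* **relationship**: 1.0 when a causality cue is present (`-induced`,
  `-associated` suffix cues; `treatment-related`, `due to`,
  `attributed to`, … phrase cues) and no negation guard
  (`no treatment-related`, `not associated with`, …) matches; else 0.0.
  Hard scores are sufficient because downstream logic only thresholds
  them; thresholds compare inclusively (≥).
* **NER**: DRUG spans from the query lexicon, AE spans from an
  adverse-event vocabulary plus the always-serious term list; overlapping
  same-type spans resolve to the longest.
* **seriousness**: `serious` on any regulatory outcome cue (death,
  life-threatening, hospitalisation, disability, congenital anomaly
  vocabulary) or always-serious term; `important_medical_event` when ADR
  evidence exists without a serious outcome; else `none`.

All cue lists are plain-text package data, overridable per run. The
relationship positivity threshold (0.2) and the NER gate (0.5) are
independent config values; with the baseline's hard scores the gap
between them is unobservable, but transformer backends produce graded
scores where it matters, so both knobs are exposed.

A transformer backend (fine-tuned per task with learning rate 3e-5,
Adam, batch size 16, 8:1:1 split; UMLS-pretrained base for relationship,
PubMed-pretrained for NER and seriousness) plugs into the same contract
via the registry. It ships as an adapter stub only — no weights — and the
test suite never depends on it.

## Decision order and rescue rules

Relationship classification runs before NER: the relationship gate is the
cheaper of the two ways to shed units, and entity extraction on
relationship-negative units is wasted work. The generic regexes run
before any classifier on every drug-containing unit because they are
nearly free and patch a known classifier failure mode — non-specific AE
mentions ("TRAEs", "adverse events") that carry no entity an NER model
can anchor on. A generic AE hit therefore both forces the relationship
gate open and counts as AE evidence (a synthetic span with
`source="regex"`). Acronym regexes are case-sensitive (AE/AEs, TRAE/TRAEs,
SAE/SAEs) to avoid matching inside ordinary words; phrase families are
case-insensitive; the grade pattern accepts grade 4, 5 and 4/5 with
reaction-family nouns.

The always-serious rescue list (pneumonia, ventricular fibrillation,
intracranial bleeding, teratogenic effects, …, each with its outcome
category) is fuzzy-matched only on units whose seriousness label is not
`serious` — the one place lexical knowledge can overrule the classifier —
and a rescue match alone is sufficient serious evidence. Generic serious
regex evidence is likewise sufficient on its own; requiring classifier
confirmation on top would forfeit exactly the recall these rules exist to
recover.

`hit_score` is the relationship score: it is the only graded,
unit-level quantity all backends produce. The ranking formula
`w1·max(hit_score) + w2·log2(1+n_hits)` (defaults 1.0 / 0.1) uses the
hit-count term as a logarithmic tie-breaker so that evidence volume
matters but can never outrank a stronger best sentence by itself; ties
break on `doc_id` for reproducible output. Documents older than the
trailing `years_window` (6 years) can be dropped at ingest; undated
documents are kept, since dropping them silently hides potentially
relevant records.

## Evaluation

Sentence-level precision/recall/F1 are computed over meaning-unit ids
(scikit-learn under the hood, cross-checked in the tests against a
hand-counted confusion matrix); units missing from the predictions count
as negative, predicted hits outside the gold set as false positives.
The per-section breakdown reports one row per observed label plus an
overall row whose volume equals the sum of section volumes. At document
level only precision is reported: estimating document recall would
require an unbiased sample of all relevant documents in the literature,
which is not obtainable at this scale, so the package does not pretend to
compute it. Zero denominators yield 0.0 with a warning rather than NaN.

## Synthetic corpora

The generator emulates the *statistical shape* of the triage workload,
not real prose: sectioned documents of short template sentences where
hits are rare (default rate 0.002 of meaning units, the imbalance
observed in drug-centred literature pulls; the bundled study
configuration uses 0.01 over ≈5,000 units so that seeded runs contain a
two-digit number of hits) and distractors share features with hits
without satisfying the full conjunction: non-serious ADRs (drug + cue +
mild AE), negated statements, generic AE mentions with and without a
drug, serious events without a drug, and neutral filler. Every sentence
comes from a template with a known label, so gold labels are exact by
construction and validated by an independent lexical check in the tests,
not by the pipeline under evaluation. All templates exceed the merge
band (≥ 11 words), so meaning units map one-to-one onto generated
sentences and gold labels key directly on unit ids; the generator asserts
this alignment. The whole corpus is a pure function of the seed.

What passing on this corpus shows: the decision diagram, thresholds,
regex rules, rescue path, ranking, funnel accounting and evaluation
machinery are internally correct and deterministic, and the baseline
backend is consistent with vocabularies it shares with the generator.
What it does not show: classification performance on real biomedical
prose — paraphrase, hedging, anaphora, cross-sentence relations and
vocabulary drift are exactly what the transformer backend exists for and
are absent from templates by design.

## Numerical and degenerate-input choices

All thresholds compare inclusively. Empty text yields no sentence spans;
empty sections yield no units; an empty corpus runs end-to-end and
produces empty outputs with a warning. Matching operates on a
length-preserving lowercase transform so offsets always index the
original text. Fuzzy gaps are measured end-of-previous-token to
start-of-next-token, 0 ≤ gap ≤ 20. Lexicon loading deduplicates
synonyms silently (counted in the load report); malformed corpus records
are skipped and counted, never fatal; unreadable files are fatal.

## Known limitations

* One relationship label per unit: two drugs and two events in one unit
  cannot be disentangled into pairs.
* The rule-based backend's cue lists are small and English-only; its
  perfect scores on synthetic corpora are a property of shared
  vocabularies, not a performance claim.
* The sentence splitter's protected list is finite; unusual
  abbreviations can still split early (the merge rule then usually
  repairs the damage downstream).
* Document recall is unmeasured by design (see Evaluation).
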