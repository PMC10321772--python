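# Methods

This note records the modelling choices behind `truthsearch`: what the
pipeline computes, which knobs matter, what the synthetic benchmark does
and does not emulate, and where the design was genuinely open.

## Retrieval and fusion

Topicality is Okapi BM25 over lowercased alphanumeric tokens (internal
hyphens kept, so `covid-19` is one term). The idf uses the natural
logarithm and is **not clamped**: a term occurring in more than half the
collection contributes negatively, exactly as the raw formula says. Any
log base rescales all scores uniformly and leaves rankings unchanged, so
the choice is cosmetic but documented for reproducibility. Defaults
k₁ = 1.2, b = 0.75 follow the common Okapi convention and are
configurable. Documents scoring exactly zero are excluded from result
lists; ties break by ascending document id. No stopwords are removed by
default (an optional list can be supplied).

The truthfulness score `its(q,d)` is a rank-weighted sum of cosines
between the whole-document embedding and the embeddings of the top-k
journal articles retrieved for the same query. Three weight schemes
satisfy the normalization and monotonicity constraints (Σwᵢ = 1,
wᵢ ≥ wᵢ₊₁): `reciprocal` (wᵢ ∝ 1/i, the default — it emphasizes the
best-matching evidence), `linear`, and `uniform`.

BM25 is unbounded while `its` lies in [−1, 1], so fusing them raw makes
the importance weights incomparable. By default topicality is min-max
normalized **within the retrieved list** before fusion; the literal
unnormalized combination is available as
`topicality_normalization: none`. When every retrieved document ties on
topicality the normalized value is defined as 1.0. Default fusion
weights are w_trs = w_its = 0.5. If no journal article is retrieved for
a query, truthfulness falls back to 0 for every document and a warning
is logged.

## Embeddings and NER

The reference embedding is signed feature hashing: each token maps
(keyed by the seed) to one of `dim` coordinates with a ±1 sign, and a
text embeds as the L2-normalized sum. It is deterministic, respects
token overlap, and keeps disjoint vocabularies near-orthogonal
(collision probability ≈ 1/dim per token pair; default dim = 512).
It captures no synonymy or word order — it is the desk-scale stand-in
for transformer sentence encoders, which plug in behind the same
`embed(text)` contract. When two backends are active (e.g. a general
and a biomedical encoder), their **cosines are averaged**; combining at
the similarity level rather than concatenating vectors keeps backends
of different dimensionality interchangeable.

The reference NER is dictionary-driven with token-boundary phrase
matching over medication and disease term lists. Entity correspondence
is **strict set equality per category** (the literal reading of profile
equality); two empty profiles match, since the absence of entities
leaves nothing to penalize. A laxer non-empty-intersection mode exists
for texts mentioning many entities. The discount weight default
w_d = 0.5 halves a mismatched similarity without annihilating it —
mismatched sentences can still surface when nothing better exists.

## Explanations

Passages are single sentences, segmented by a deterministic rule (split
after terminal punctuation, abbreviation guard list, spans tile the
source text). The three similarity strategies score a (query, sentence)
pair with statistics fitted on the sentence population being searched:
TF-IDF idf tables come from the sentences of the document being
explained (for passages) or of the retrieved journal articles (for
evidence); the BM25 strategy treats each sentence as a document of a
sentence-level index. Evidence extraction uses the **passage text as
the query** — the topic itself is not re-used at that stage — because
the evidence is meant to support the specific claim shown to the user,
not the topic in general. Ties break by source order (sentence index,
then journal rank), which makes rankings reproducible and invariant to
input sentence permutation.

## Classification evaluation

A document's score aggregates the σ similarities of its top-P passages'
evidence: per passage, the mean or max over its E evidence scores;
across passages, a combine rule that defaults to mirroring the mode
(max with max, mean with mean) and can be overridden. The only fitted
quantity is the decision threshold θ, chosen on the training folds to
maximize F1 over the grid of midpoints between consecutive sorted
unique scores (ties → smallest θ; if the training scores collapse to a
single value, θ is that value and a warning is logged). The positive
class is *credible*, used as the proxy for *truthful*.

Metrics: F1 = 2TP/(2TP+FP+FN) with the TP=FP=FN=0 case defined as 1.0;
GM = √(sensitivity × specificity); AUC is the Mann–Whitney
pairwise-ordering statistic with ties counted ½ (computed via
`roc_auc_score`, which implements exactly that convention, and verified
against an O(n²) oracle in the tests). Cross-validation shuffles
(topic, document) pairs with the seed and splits them into folds whose
sizes differ by at most one; a held-out fold with single-class labels
reports AUC as NaN and NaN-aware means are taken. Fleiss' kappa is
implemented directly because its degenerate case (expected agreement
P_e = 1) needs a defined answer: κ = 1 when observed agreement is also
perfect, an error otherwise; the tests cross-check against the
statsmodels implementation on non-degenerate tables.

## The synthetic benchmark

Each topic pairs a medication and a disease in a fact sentence
("X is an effective treatment option for Y according to recent peer
reviewed studies"). The topic's journal article embeds the fact
verbatim in formal filler prose. Truthful documents (credibility 1)
carry a token-dropout paraphrase of the fact (rate 0.1 per non-entity
token; entity tokens are never dropped) inside casual filler prose.
Misinformation documents (credibility 0, half of each topic's 40
documents by default) carry the same paraphrase after corruption:
`entity_swap` (default) replaces the medication with a different
vocabulary term, `negation` inserts "not", `random_text` drops the
claim entirely.

Two properties are deliberate:

* **Document and journal filler pools are lexically disjoint.** A shared
  filler sentence appearing verbatim on both sides would give an
  entity-free passage/evidence pair σ = 1 and destroy the separability
  of the benchmark.
* **Misinformation receives the same paraphrase noise as truthful
  text.** Under entity swap, the undiscounted cosine of a corrupted
  sentence against the journal fact (≈ 0.9) then overlaps the truthful
  range (≈ 0.85–1.0), so similarity alone cannot separate the classes —
  while the NER discount pushes corrupted evidence below ≈ 0.5 and
  restores perfect separation. Passing the mechanism-recovery test
  therefore demonstrates that the entity check, not raw lexical
  similarity, drives the improvement.

What the generator does **not** emulate: real linguistic variety,
claim stance or hedging, adversarial misinformation that preserves
entities while inverting meaning (the `negation` mode defeats the NER
discount by design), topic drift, or the label noise of human
credibility judgements. Perfect scores on the benchmark show the
pipeline recovers the mechanism it encodes, not that comparable
numbers would be reached on crawled web data with transformer
embeddings.

## Problem sizes and numerics

The default study conditions are 8 topics × 40 documents (320 labeled
pairs), one journal article per topic, P = 5 passages, E = 5 evidence
sentences, five folds — sizes at which the full pipeline, test suite,
and acceptance script each run in seconds on one CPU while keeping
every per-topic fold populated. Floating-point summation orders are
fixed (query terms in first-occurrence order, fold indices from the
seeded permutation), so identical configs and seeds produce
byte-identical run, explanation, and metric files. Oracle-equivalence
tests use 1e-9 absolute tolerance; invariant checks use 1e-12 slack for
accumulated rounding.

## Known limitations

* Whole-document embeddings dilute long documents; there is no sliding
  window or length truncation beyond what the backend does.
* Dictionary NER cannot find entities outside its term lists, and the
  strict-equality match penalizes sentences that mention a superset of
  the query's entities.
* The threshold grid contains only interior midpoints, so a training
  fold whose optimum is "predict everything positive" is represented
  only up to the smallest midpoint.
* BM25 idf can be zero or negative in tiny collections (N ≤ 2 with
  df = 1 gives idf = ln 1 = 0), which makes minimal examples behave
  unintuitively; fixtures should use at least three documents.
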