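# Methods

This note documents the models and procedures implemented in `medrelex`,
the defaults that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Preprocessing

**Tokenization.** Two modes share one scanner (letter-initial alphanumeric
runs are words, digit runs are numbers, any other non-space character is a
single punctuation token). `annie_compatible` keeps whitespace runs as
tokens, so surfaces concatenate back to the input exactly and the phrase
"disease and diagnosis." counts 6 tokens (word, space, word, space, word,
period); `compact` drops space tokens and is what feature extraction uses.
Offsets are 0-based, half-open, which keeps span arithmetic unambiguous.

**Sentence splitting.** A boundary falls after `.`/`!`/`?` when followed by
whitespace or end of input, unless the contiguous word-with-period run
ending there (e.g. "e.g.") is in the abbreviation dictionary (shipped as
`data/abbreviations.txt`, one entry per line, editable). Requiring a
following gap means internal periods ("e.g" ↦ "."` ↦ "g") never split. The
shipped abbreviation list is this package's choice of a reasonable default,
not a reproduction of any particular tool's list.

**POS tagging.** The tagset is Penn Treebank. The default backend is a
deterministic rule tagger: a shipped lexicon of closed-class and common
domain words, then suffix heuristics (-ly → RB, -ing → VBG, -ed → VBD,
plural -s → NNS), with NN as the fallback. The NN fallback is deliberate:
out-of-vocabulary biomedical tokens (gene names like "Pop1p", drug names,
generated pseudo-words) land inside noun phrases, which is where they belong
for this task. The backend is pluggable behind `get_tagger`; requesting an
unavailable backend raises a configuration error naming it. Any replacement
must reproduce the documented examples ("disease" → NN, "bind" → VBP in the
twelve-word chunking example).

**Lemmatization.** An ordered suffix-rule table (`data/suffix_rules.tsv`,
`pos_class<TAB>suffix<TAB>replacement`, first match wins) keyed by POS class:
plural stripping for nouns (`-ies → y`, sibilant `-es` forms, plain `-s`,
with an identity guard for `-ss`), and `-ing`/`-ed`/`-s` stripping for verbs
with an e-restoration stem list (`smok → smoke`, `caus → cause`) and a
doubled-consonant reduction (`runn → run`; `s` and `l` are exempt to keep
`pass`/`tell` intact). A small irregular table covers be/have/do/go and a
few irregular plurals. The rules are heuristic by construction — "goes"
without the irregular table would strip to "goe" — but they are the contract:
they are idempotent (property-tested over fuzzed words) and reproduce the
documented examples (smoking → smoke, causes → cause, subunits → subunit).

## Chunking

The default backend is a deterministic grammar over Penn tags:

* **NP** — optional leading RB when it modifies a following DT/CD/JJ
  ("Only two protein subunits"), then a run of DT/PDT/CD/JJ* tokens headed
  by at least one NN*; a CC is absorbed when both flanks are nominal, so
  "Pop1p and Pop4p" and "efficacy and safety" stay single chunks.
* **VP** — a run of MD/VB* with trailing RBs absorbed. A pre-verbal adverb
  ("specifically bind") is adverbial, not part of the VP.

Chunks never cross punctuation, are disjoint, and appear in sentence order.
Where published chunker outputs disagree on such sentences, this grammar
follows the biomedical-tagger convention (coordination kept inside the NP).

Phrase cleanup (`phrase_to_feature`) lowercases, lemmatizes, and drops
stopwords and punctuation-only words; a chunk whose words are all stopwords
yields no feature. The stopword list is a standard ~130-word English list
shipped as `data/stopwords.txt` and is configurable — no particular
published list is canonical for this task.

An important asymmetry: the dimension count *q* used by concept ranking is
the **original** phrase's word count, never the cleaned feature's. "the RNA
subunit" has q = 3 even though its feature is "rna subunit".

## Concept ranking

The lexicon emulates concept-mapping output: `term → [{concept, score,
types, matched?}]`, scores on the MetaMap 0–1000 scale (fixed positive
convention), `matched` optional word-offset indices relative to the term
(defaulting to all of the term's word positions within the queried phrase).
`map_phrase` looks up the full phrase string and each word dimension
(surface first, lemma as fallback), merges duplicate concepts by unioning
their matched-word sets, and orders candidates by score descending, then
concept name — so mapping is fully deterministic.

Filters, in order:

1. **F1** score ≥ 600 (NP) / ≥ 700 (VP); boundaries are inclusive, so a
   score of 599 fails an NP threshold of 600.
2. **F2** at least one semantic type in the allow-list. The default
   allow-list is the eleven types that appear in the documented mapping
   examples (Therapeutic or Preventive Procedure, Functional Concept,
   Qualitative Concept, Human-caused Phenomenon or Process, Research
   Activity, Activity, Mental Process, Medical Device, Diagnostic
   Procedure, Body Location or Region, Quantitative Concept); an empty
   allow-list disables F2. This is a configurable default, not a closed
   inventory.
3. **F3** is a phrase-level gate computed on the F1∧F2 survivors: the union
   of their matched dimensions must cover at least q − 1 of the phrase's q
   word dimensions, otherwise the phrase contributes nothing. This
   interpretation (coverage by the union, one uncovered function word
   allowed) is what makes the "efficacy and safety" example work: q = 3,
   "and" unmapped, coverage 2 = q − 1, phrase accepted. F3 failing removes
   only the phrase's *ranked* feature; its plain NLP phrase feature at the
   `BOW_NLP` level is unaffected.

The top survivor by (score, then lexicographic concept name) is attached as
metadata; **the cleaned phrase string is the emitted feature**, not the
concept name. The selection examples point to the phrase being chosen as the
feature, and phrase identity also keeps the feature space stable when the
lexicon's concept inventory changes; the concept name is retained on the
`RankedConcept` for inspection.

## Features and vectors

Feature levels are strictly cumulative: `BOW` (lemmatized, stopword- and
punctuation-free unigrams; number tokens kept as-is), `BOW_NLP` (+ `np:` /
`vp:` phrase features), `BOW_NLP_UMLS_NP` (+ `unp:` ranked NPs),
`BOW_NLP_UMLS_NP_VP` (+ `uvp:` ranked VPs). Prefixes namespace phrase terms
away from their constituent unigrams so "rna subunit" the phrase and
"rna"/"subunit" the unigrams are distinct dimensions — without this, phrase
and unigram strings would silently collide.

Vectors are binary term presence (1 iff the term occurs at least once),
chosen over frequency and TF-IDF weighting, which are not implemented. The
vocabulary is the sorted union of **training-fold** bags only;
out-of-vocabulary test terms are ignored. Training-only construction is
required for leakage-free cross-validation.

## Classifiers

**Naïve Bayes** is a Bernoulli-event-model implementation written from the
closed form: P(c) = n_c/n, P(d_j = 1|c) = (n_jc + α)/(n_c + 2α) with
Laplace α = 1 by default, prediction in log space over *all* vocabulary
dimensions (absent terms contribute P(d_j = 0|c)), ties broken toward the
smallest class id. The Bernoulli model is the natural match for binary
presence features, and smoothing is mandatory: a single unseen term would
otherwise zero the product. Tests verify exact agreement with a pure
product-form evaluation on all 2⁸ vectors of an 8-term vocabulary and with
an independent reference implementation.

**SVM** delegates to libsvm (via scikit-learn's `SVC`) behind a thin
`svm_train`/`svm_predict` contract with two presets: linear kernel at
cost 0.5, and RBF at cost 8 with γ = 0.05. Other solver parameters stay at
libsvm defaults (tolerance 1e-3, shrinking on, no class weighting), and no
feature scaling is applied — inputs are already 0/1. All evaluation settings
are binary, so no multiclass decomposition is needed.

## Evaluation protocol

Nine binary tasks: each relation (cure, prevent, side_effect) versus
(1) DisOnly + TreatOnly, (2) Vague, (3) the other meaningful relations
(cure vs. prevent + side_effect; prevent vs. side_effect; side_effect vs.
prevent). Records outside the two sides are excluded; an empty side is an
error.

Cross-validation is stratified and deterministic: per class, indices are
shuffled by a seeded generator and dealt round-robin into k folds (default
k = 10, seed 42). If the smallest class has fewer than k members, k is
reduced to that count with a logged warning — stratification is what lets a
class of a few dozen sentences appear in every fold. Metrics are computed
for the positive class from each test fold's confusion counts (zero
denominators yield 0) and **averaged arithmetically over folds** (not pooled),
reported in percent with two decimals. Reports (TSV and JSON) embed the
seed, k, fold assignments, and the effective run configuration, so any
reported number can be regenerated exactly.

## Synthetic data

The generator emulates the *shape* of a disease–treatment sentence corpus,
not its language. Each sentence is rendered from a fixed taggable template —
`the <subject> <verb> the <object> [with <noise>…] .` — with subjects and
objects drawn from a shared 10-noun pool, a per-class VP cue (a verb) and NP
cue (a two-word phrase) substituted with a configurable emission
probability, and noise pseudo-words drawn from a shared generated
vocabulary. The default study corpus has six classes (Cure, Prevent,
SideEffect, DisOnly, TreatOnly, Vague), 100 sentences per class, cue
probability 1.0 and zero noise — i.e. perfectly separable by construction —
because that is the regime in which the end-to-end pipeline must provably
score 100% at every feature level; tests then lower cue probability and
raise noise to verify graceful degradation. The matching lexicon generator
gives cue words/phrases entries scored in [700, 1000] with allow-listed
types (coverage probability 1.0 by default) and gives noise/filler words
sub-threshold entries in [0, 599], so filter F1 separates signal from noise
by design.

A second preset (`phrase_signal_config`, 2 × 30 sentences) places the class
signal *only* in word order inside the object NP ("alpha beta" vs. "beta
alpha"): unigram content is identical across classes, so bag-of-words
carries no signal while phrase-level features separate the classes — this
is the design used to demonstrate the value of concept-ranked phrase
features over plain BOW (mean F over 10 seeds, ranked-phrase level ≥ BOW).

What passing these tests shows: the pipeline's plumbing, filters, vectors,
classifiers and CV protocol are correct and deterministic, and phrase-level
features add exactly the signal they are designed to add. What it does not
show: performance on real biomedical language, whose tagging/chunking
ambiguity, vocabulary burstiness and label noise the templates deliberately
do not model. Numbers obtained on synthetic corpora are not comparable to
published corpus results.

## Numerical and degenerate-input choices

* All randomness flows through named `numpy` generators seeded explicitly;
  fixed seeds give byte-identical corpora, lexica, folds and reports.
* NB posteriors are normalized in log space; normalization is tested to
  1e-9. Argmax ties resolve to the smallest class id.
* Score thresholds and the F3 gate use inclusive ≥ comparisons.
* Empty text tokenizes to an empty list; a sentence with no word tokens
  tags to itself, chunks to nothing, and yields empty bags at every level.
* `q = 1` phrases pass F3 vacuously (q − 1 = 0) and are governed by F1/F2
  alone.
* Concept-candidate matched indices outside 0..q−1 raise an integrity
  error rather than being clipped.

## Problem sizes used in the checks

The separability acceptance run uses the default six-class corpus (600
sentences, 100 per class) on setting 1/cure with all four feature levels,
Naïve Bayes and the linear SVM under 10-fold CV; the phrase-signal
comparison uses 10 seeds × 60 sentences; filter-oracle and monotonicity
fuzzing use 500 and 100 random cases with q ≤ 4 and ≤ 6 candidates. These
sizes make every documented property decidable exactly while keeping the
full suite fast enough to run on every change.

## Known limitations

* The rule tagger and chunker are deterministic approximations; sentences
  far from the template grammar (questions, heavy nesting, parentheticals)
  will chunk imperfectly. Both are pluggable backends.
* The lemmatizer is a suffix heuristic with a finite e-restoration list;
  rare inflections lemmatize to non-words (harmless for classification,
  since the mapping is consistent).
* The biotext reader dialect and label alias table are best-effort against
  externally distributed label spellings; the alias table is a shipped,
  editable data file.
* Live concept-mapping (MetaMap) access is intentionally out of scope; the
  lexicon JSON is the integration point.
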