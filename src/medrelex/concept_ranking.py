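"""Concept ranking of noun and verb phrases against a MetaMap-style lexicon.

A phrase is mapped to candidate concepts (each with a name, an integer score
on the 0-1000 MetaMap scale, and UMLS semantic types) and then pushed through
three filters:

* F1 — score threshold, kind-specific: NP candidates need score >= 600, VP
  candidates score >= 700 (both configurable).
* F2 — semantic-type allow-list: at least one of the candidate's types must
  be allowed (an empty allow-list passes everything).
* F3 — dimension coverage: of the phrase's q word dimensions, at least q-1
  must be covered by the union of matched words over the F1∧F2 survivors.
  F3 is a phrase-level gate: if it fails, the phrase yields no concepts at
  all. The canonical example is the 3-word NP "efficacy and safety", where
  "efficacy" and "safety" map but "and" does not: coverage 2 = q-1, so the
  phrase qualifies.

The single top-scoring survivor (ties broken lexicographically by concept
name) is selected, and the *phrase* — cleaned per the phrase-feature rules —
is what enters the classifier's feature space; the concept is kept as
metadata. Scores are consumed, never computed: the lexicon emulates MetaMap
mapping output and can be swapped for a live MetaMap adapter behind the same
term → candidates contract.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .chunking import PhraseChunk, PhraseFeature, phrase_to_feature
from .exceptions import DataFormatError, IntegrityError
from .preprocess import SuffixRules, lemmatize

#: Semantic types appearing in the documented mapping examples; fully
#: configurable because real MetaMap output uses many more.
DEFAULT_ALLOWED_TYPES = frozenset(
    {
        "Therapeutic or Preventive Procedure",
        "Functional Concept",
        "Qualitative Concept",
        "Human-caused Phenomenon or Process",
        "Research Activity",
        "Activity",
        "Mental Process",
        "Medical Device",
        "Diagnostic Procedure",
        "Body Location or Region",
        "Quantitative Concept",
    }
)


@dataclass(frozen=True)
class ConceptCandidate:
    """One candidate concept for a phrase, with the word dimensions it covers."""

    concept_name: str
    score: int
    semantic_types: tuple[str, ...]
    matched_words: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1000:
            raise ValueError(f"score must be in [0, 1000], got {self.score}")
        if not self.semantic_types:
            raise ValueError("a concept candidate needs at least one semantic type")


@dataclass(frozen=True)
class LexiconEntry:
    """A lexicon term with its raw candidate specs (matched indices unbound)."""

    term: str
    candidates: tuple[Mapping, ...] = ()


Lexicon = Mapping[str, LexiconEntry]


@dataclass(frozen=True)
class RankerConfig:
    np_threshold: int = 600
    vp_threshold: int = 700
    allowed_semantic_types: frozenset[str] = DEFAULT_ALLOWED_TYPES
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        for name in ("np_threshold", "vp_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1000:
                raise ValueError(f"{name} must be in [0, 1000], got {v}")

    def threshold(self, kind: str) -> int:
        return self.np_threshold if kind == "NP" else self.vp_threshold


@dataclass(frozen=True)
class RankedConcept:
    """A phrase selected as a classification feature, with its top concept."""

    phrase: PhraseFeature
    concept: ConceptCandidate


def load_lexicon(source: Union[str, Path, Mapping]) -> dict[str, LexiconEntry]:
    """Load a lexicon from a JSON file (or an equivalent mapping).

    Format: term -> list of {"concept": str, "score": int, "types": [str],
    "matched": [int] (optional, relative to the term's position in the
    queried phrase)}.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = json.loads(Path(source).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise DataFormatError(f"lexicon {source}: invalid JSON ({exc})") from exc
    else:
        raw = source
    if not isinstance(raw, Mapping):
        raise DataFormatError("lexicon must be a JSON object mapping term -> candidates")
    lex: dict[str, LexiconEntry] = {}
    for term, cands in raw.items():
        if not term:
            raise DataFormatError("lexicon terms must be non-empty strings")
        specs = []
        for c in cands:
            missing = {"concept", "score", "types"} - set(c)
            if missing:
                raise DataFormatError(
                    f"lexicon entry {term!r}: candidate missing keys {sorted(missing)}"
                )
            specs.append(dict(c))
        lex[term.lower()] = LexiconEntry(term=term.lower(), candidates=tuple(specs))
    return lex


def _phrase_dimensions(phrase: PhraseChunk, rules: Optional[SuffixRules]) -> list[tuple[str, str]]:
    """(lowercased surface, lemma) per word dimension of the phrase."""
    dims = []
    for tok in phrase.word_tokens:
        surface = tok.surface.lower()
        lemma = tok.lemma or lemmatize(tok.surface, tok.pos_tag or "", rules)
        dims.append((surface, lemma))
    return dims


def _bind_candidates(
    entry: LexiconEntry, offset: Optional[int], term_width: int, q: int
) -> list[ConceptCandidate]:
    """Turn raw candidate specs into ConceptCandidates with absolute matched indices.

    ``offset`` is the dimension index where the term starts (None = the full
    phrase, i.e. offset 0 and width q).
    """
    start = 0 if offset is None else offset
    width = q if offset is None else term_width
    out = []
    for spec in entry.candidates:
        matched = spec.get("matched")
        if matched is None:
            indices = frozenset(range(start, start + width))
        else:
            indices = frozenset(start + int(d) for d in matched)
        out.append(
            ConceptCandidate(
                concept_name=str(spec["concept"]),
                score=int(spec["score"]),
                semantic_types=tuple(spec["types"]),
                matched_words=indices,
            )
        )
    return out


def map_phrase(
    phrase: PhraseChunk,
    lexicon: Lexicon,
    rules: Optional[SuffixRules] = None,
) -> list[ConceptCandidate]:
    """Candidates for the full phrase string and for each word dimension.

    Each word is looked up by lowercased surface, falling back to its lemma.
    Candidates are deduplicated (matched-word sets merged) and returned in
    deterministic order: score descending, then concept name.
    """
    dims = _phrase_dimensions(phrase, rules)
    q = len(dims)
    merged: dict[tuple[str, int, tuple[str, ...]], set[int]] = {}

    def add(cands: Sequence[ConceptCandidate]) -> None:
        for c in cands:
            key = (c.concept_name, c.score, c.semantic_types)
            merged.setdefault(key, set()).update(c.matched_words)

    full = " ".join(surface for surface, _ in dims)
    entry = lexicon.get(full)
    if entry is not None:
        add(_bind_candidates(entry, None, q, q))
    for i, (surface, lemma) in enumerate(dims):
        entry = lexicon.get(surface) or (lexicon.get(lemma) if lemma != surface else None)
        if entry is not None:
            add(_bind_candidates(entry, i, 1, q))

    out = [
        ConceptCandidate(name, score, types, frozenset(matched))
        for (name, score, types), matched in merged.items()
    ]
    out.sort(key=lambda c: (-c.score, c.concept_name))
    return out


def dimension_coverage(
    phrase: PhraseChunk,
    candidates: Sequence[ConceptCandidate],
    config: Optional[RankerConfig] = None,
) -> frozenset[int]:
    """Word dimensions covered by the union of F1∧F2 survivors."""
    if config is None:
        config = RankerConfig()
    covered: set[int] = set()
    for c in _f1_f2_survivors(phrase, candidates, config):
        covered.update(c.matched_words)
    return frozenset(covered)


def _f1_f2_survivors(
    phrase: PhraseChunk, candidates: Sequence[ConceptCandidate], config: RankerConfig
) -> list[ConceptCandidate]:
    thr = config.threshold(phrase.kind)
    allowed = config.allowed_semantic_types
    q = phrase.q
    out = []
    for c in candidates:
        bad = [d for d in c.matched_words if not 0 <= d < q]
        if bad:
            raise IntegrityError(
                f"candidate {c.concept_name!r} matches dimensions {sorted(bad)} "
                f"outside the phrase's 0..{q - 1} range"
            )
        if c.score < thr:
            continue
        if allowed and not set(c.semantic_types) & allowed:
            continue
        out.append(c)
    return out


def apply_filters(
    phrase: PhraseChunk,
    candidates: Sequence[ConceptCandidate],
    config: Optional[RankerConfig] = None,
) -> list[ConceptCandidate]:
    """Apply F1 (score), F2 (semantic type) and the F3 phrase-level coverage gate."""
    if config is None:
        config = RankerConfig()
    survivors = _f1_f2_survivors(phrase, candidates, config)
    covered: set[int] = set()
    for c in survivors:
        covered.update(c.matched_words)
    if len(covered) < phrase.q - 1:
        return []
    return survivors


def select_top_concept(
    survivors: Sequence[ConceptCandidate],
    config: Optional[RankerConfig] = None,
) -> Optional[ConceptCandidate]:
    """Maximum-score survivor; ties broken lexicographically by concept name."""
    if not survivors:
        return None
    return min(survivors, key=lambda c: (-c.score, c.concept_name))


def rank_phrases(
    chunks: Sequence[PhraseChunk],
    lexicon: Lexicon,
    config: Optional[RankerConfig] = None,
    stopwords: Optional[frozenset[str]] = None,
    rules: Optional[SuffixRules] = None,
) -> list[RankedConcept]:
    """map → filter → select per chunk; one RankedConcept per surviving chunk."""
    if config is None:
        config = RankerConfig()
    out: list[RankedConcept] = []
    for chunk in chunks:
        candidates = map_phrase(chunk, lexicon, rules)
        survivors = apply_filters(chunk, candidates, config)
        top = select_top_concept(survivors, config)
        if top is None:
            continue
        feature = phrase_to_feature(chunk, stopwords, rules)
        if feature is None:
            continue
        out.append(RankedConcept(phrase=feature, concept=top))
    return out
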