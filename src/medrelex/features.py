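"""Feature-set assembly and binary term-presence vectorization.

Four cumulative feature levels are supported:

* ``BOW`` — lemmatized, stopword- and punctuation-free unigrams;
* ``BOW_NLP`` — adds cleaned NP/VP phrase features (``np:``/``vp:`` prefixed);
* ``BOW_NLP_UMLS_NP`` — adds NP phrases that survive concept ranking
  (``unp:`` prefixed);
* ``BOW_NLP_UMLS_NP_VP`` — adds ranked VP phrases as well (``uvp:``).

Phrase features are namespaced so that the phrase "rna subunit" and the
unigrams "rna"/"subunit" occupy distinct vector dimensions. Instances become
binary vectors over a vocabulary built from training data only: component i
is 1 iff term i occurs at least once in the instance's feature bag.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .chunking import chunk_sentence, default_stopwords, phrase_to_feature
from .concept_ranking import Lexicon, RankerConfig, rank_phrases
from .exceptions import ConfigurationError
from .preprocess import SentenceRec, SuffixRules, TokenKind, preprocess_text


class FeatureLevel(Enum):
    BOW = 0
    BOW_NLP = 1
    BOW_NLP_UMLS_NP = 2
    BOW_NLP_UMLS_NP_VP = 3

    @classmethod
    def parse(cls, name: str) -> "FeatureLevel":
        key = name.strip().upper().replace("+", "_").replace("-", "_")
        try:
            return cls[key]
        except KeyError:
            raise ConfigurationError(
                f"unknown feature level {name!r}; choose from "
                f"{[lv.name for lv in cls]}"
            ) from None


def extract_instance_features(
    sentence: SentenceRec,
    level: FeatureLevel = FeatureLevel.BOW,
    lexicon: Optional[Lexicon] = None,
    config: Optional[RankerConfig] = None,
    stopwords: Optional[frozenset[str]] = None,
    rules: Optional[SuffixRules] = None,
) -> list[str]:
    """Feature bag of one preprocessed (tagged + lemmatized) sentence."""
    if stopwords is None:
        stopwords = default_stopwords()
    bag: list[str] = []
    for tok in sentence.tokens:
        if tok.kind is TokenKind.WORD:
            lemma = tok.lemma or tok.surface.lower()
            if lemma not in stopwords and tok.surface.lower() not in stopwords:
                bag.append(lemma)
        elif tok.kind is TokenKind.NUMBER:
            bag.append(tok.surface)
    if level is FeatureLevel.BOW:
        return bag

    chunks = chunk_sentence(sentence)
    for chunk in chunks:
        feature = phrase_to_feature(chunk, stopwords, rules)
        if feature is not None:
            bag.append(f"{feature.kind.lower()}:{feature.text}")
    if level is FeatureLevel.BOW_NLP:
        return bag

    if lexicon is None:
        raise ConfigurationError(
            f"feature level {level.name} requires a concept lexicon"
        )
    kinds = ("NP",) if level is FeatureLevel.BOW_NLP_UMLS_NP else ("NP", "VP")
    ranked = rank_phrases(
        [c for c in chunks if c.kind in kinds], lexicon, config, stopwords, rules
    )
    for rc in ranked:
        bag.append(f"u{rc.phrase.kind.lower()}:{rc.phrase.text}")
    return bag


def extract_text_features(
    text: str,
    level: FeatureLevel = FeatureLevel.BOW,
    lexicon: Optional[Lexicon] = None,
    config: Optional[RankerConfig] = None,
    stopwords: Optional[frozenset[str]] = None,
    rules: Optional[SuffixRules] = None,
    source_id: str = "",
) -> list[str]:
    """Preprocess raw text and concatenate the bags of its sentences."""
    bag: list[str] = []
    for sent in preprocess_text(text, source_id=source_id, rules=rules):
        bag.extend(
            extract_instance_features(sent, level, lexicon, config, stopwords, rules)
        )
    return bag


@dataclass(frozen=True)
class Vocabulary:
    """Ordered unique feature strings with their 0-based positions."""

    terms: tuple[str, ...]

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


def build_vocabulary(training_bags: Sequence[Sequence[str]]) -> Vocabulary:
    """Sorted union of the training bags' terms; deterministic."""
    if not training_bags:
        raise ValueError("cannot build a vocabulary from an empty training set")
    terms: set[str] = set()
    for bag in training_bags:
        terms.update(bag)
    if not terms:
        raise ValueError("training bags contain no features")
    return Vocabulary(terms=tuple(sorted(terms)))


def vectorize(bag: Sequence[str], vocab: Vocabulary) -> np.ndarray:
    """Binary term-presence vector; out-of-vocabulary terms are ignored."""
    vec = np.zeros(len(vocab), dtype=np.int8)
    index = vocab.index
    for term in bag:
        pos = index.get(term)
        if pos is not None:
            vec[pos] = 1
    return vec


def vectorize_all(bags: Sequence[Sequence[str]], vocab: Vocabulary) -> np.ndarray:
    X = np.zeros((len(bags), len(vocab)), dtype=np.int8)
    index = vocab.index
    for row, bag in enumerate(bags):
        for term in bag:
            pos = index.get(term)
            if pos is not None:
                X[row, pos] = 1
    return X
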