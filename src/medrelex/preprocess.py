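"""Corpus preprocessing: tokenization, sentence splitting, POS tagging, lemmatization.

The four steps mirror a classic information-extraction preprocessing pipeline
for English text. Tokenization has two modes: ``annie_compatible`` keeps
whitespace runs as tokens so that the concatenation of surfaces reconstructs
the input exactly (the convention under which "disease and diagnosis." counts
6 tokens), while ``compact`` drops space tokens and is what feature extraction
uses. POS tagging is pluggable; the default backend is a deterministic
lexicon-plus-suffix rule tagger over the Penn Treebank tagset. Lemmatization
is an ordered suffix-stripping rule table keyed by POS class (noun/verb) with
an e-restoration list for verb stems; the rule table is shipped as data and is
the contract — any replacement lemmatizer must reproduce its documented
examples (smoking→smoke, causes→cause, subunits→subunit).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from ._resources import tsv_rows, word_set
from .exceptions import ConfigurationError


class TokenKind(str, Enum):
    WORD = "word"
    SPACE = "space"
    PUNCTUATION = "punctuation"
    NUMBER = "number"


@dataclass(frozen=True)
class Token:
    """A text unit with its kind, 0-based half-open character span, and annotations."""

    surface: str
    kind: TokenKind
    offset: int
    pos_tag: Optional[str] = None
    lemma: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")

    @property
    def end(self) -> int:
        return self.offset + len(self.surface)


@dataclass(frozen=True)
class SentenceRec:
    """An ordered run of tokens belonging to one sentence of a corpus record."""

    tokens: tuple[Token, ...]
    source_id: str = ""
    char_span: tuple[int, int] = (0, 0)

    @property
    def word_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.kind in (TokenKind.WORD, TokenKind.NUMBER))


# word: letter-initial run of word characters; number: digit run; any other
# non-space char is a single punctuation token.
_TOKEN_RE = re.compile(r"\s+|[^\W\d_]\w*|\d+|.", re.UNICODE)

_TERMINALS = frozenset({".", "!", "?"})


def tokenize(text: str, mode: str = "compact") -> list[Token]:
    """Split ``text`` into tokens.

    In ``annie_compatible`` mode whitespace runs are kept as space tokens and
    the surfaces concatenate back to ``text`` exactly; ``compact`` omits them.
    """
    if mode not in ("annie_compatible", "compact"):
        raise ValueError(f"unknown tokenize mode: {mode!r}")
    out: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        s = m.group(0)
        if s.isspace():
            if mode == "annie_compatible":
                out.append(Token(s, TokenKind.SPACE, m.start()))
            continue
        if s[0].isdigit():
            kind = TokenKind.NUMBER
        elif s[0].isalpha():
            kind = TokenKind.WORD
        else:
            kind = TokenKind.PUNCTUATION
        out.append(Token(s, kind, m.start()))
    return out


def default_abbreviations() -> frozenset[str]:
    return word_set("abbreviations.txt")


def _abbrev_run(tokens: Sequence[Token], i: int) -> str:
    """Surface of the offset-contiguous non-space run ending at token ``i``."""
    j = i
    while j > 0 and tokens[j - 1].kind != TokenKind.SPACE and tokens[j - 1].end == tokens[j].offset:
        j -= 1
    return "".join(t.surface for t in tokens[j : i + 1])


def split_sentences(
    tokens: Sequence[Token],
    abbreviations: Optional[Iterable[str]] = None,
    source_id: str = "",
) -> list[SentenceRec]:
    """Group tokens into sentences.

    A sentence boundary falls after a terminal ``.``/``!``/``?`` that is
    followed by whitespace or end of input, unless the contiguous word-with-
    period run ending at it (e.g. "e.g.") is in the abbreviation set.
    """
    abbrevs = (
        frozenset(a.lower() for a in abbreviations)
        if abbreviations is not None
        else default_abbreviations()
    )
    sentences: list[SentenceRec] = []
    current: list[Token] = []
    for i, tok in enumerate(tokens):
        current.append(tok)
        if tok.kind is TokenKind.PUNCTUATION and tok.surface in _TERMINALS:
            nxt = tokens[i + 1] if i + 1 < len(tokens) else None
            followed_by_gap = nxt is None or nxt.kind is TokenKind.SPACE or nxt.offset > tok.end
            if followed_by_gap and _abbrev_run(tokens, i).lower() not in abbrevs:
                if any(t.kind is not TokenKind.SPACE for t in current):
                    sentences.append(_make_sentence(current, source_id))
                current = []
    if any(t.kind is not TokenKind.SPACE for t in current):
        sentences.append(_make_sentence(current, source_id))
    return sentences


def _make_sentence(tokens: list[Token], source_id: str) -> SentenceRec:
    return SentenceRec(
        tokens=tuple(tokens),
        source_id=source_id,
        char_span=(tokens[0].offset, tokens[-1].end),
    )


class RuleTagger:
    """Deterministic Penn-Treebank tagger: shipped lexicon first, suffix heuristics after.

    Unknown words default to NN, which keeps out-of-vocabulary biomedical
    nouns (gene/protein names, drug names, generated pseudo-words) inside
    noun-phrase chunks.
    """

    def __init__(self, lexicon: Optional[Mapping[str, str]] = None) -> None:
        if lexicon is None:
            lexicon = {w: t for w, t in tsv_rows("tagger_lexicon.tsv")}
        self._lexicon = {w.lower(): t for w, t in lexicon.items()}

    def tag_word(self, surface: str, kind: TokenKind) -> str:
        if kind is TokenKind.NUMBER or surface.isdigit():
            return "CD"
        w = surface.lower()
        tag = self._lexicon.get(w)
        if tag is not None:
            return tag
        if w.endswith("ly") and len(w) > 3:
            return "RB"
        if w.endswith("ing") and len(w) > 4:
            return "VBG"
        if w.endswith("ed") and len(w) > 3:
            return "VBD"
        if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
            return "NNS"
        return "NN"


_DEFAULT_TAGGER: Optional[RuleTagger] = None


def get_tagger(backend: str = "rule") -> RuleTagger:
    """Return a tagger backend by name; only the shipped rule tagger is bundled."""
    global _DEFAULT_TAGGER
    if backend == "rule":
        if _DEFAULT_TAGGER is None:
            _DEFAULT_TAGGER = RuleTagger()
        return _DEFAULT_TAGGER
    raise ConfigurationError(
        f"POS tagger backend {backend!r} is not available; configure 'rule' "
        "or register a backend object implementing tag_word(surface, kind)"
    )


def pos_tag(sentence: SentenceRec, tagger: Optional[RuleTagger] = None) -> SentenceRec:
    """Annotate every word/number token with a Penn Treebank tag.

    Space and punctuation tokens are tagged with their own surface. A sentence
    with no word tokens is returned unchanged.
    """
    if tagger is None:
        tagger = get_tagger()
    if not sentence.word_tokens:
        return sentence
    tagged = []
    for tok in sentence.tokens:
        if tok.kind in (TokenKind.WORD, TokenKind.NUMBER):
            tagged.append(replace(tok, pos_tag=tagger.tag_word(tok.surface, tok.kind)))
        else:
            tagged.append(replace(tok, pos_tag=tok.surface))
    return replace(sentence, tokens=tuple(tagged))


# --- lemmatization -----------------------------------------------------------

_IRREGULAR_VERBS = {
    "is": "be", "am": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do",
    "goes": "go", "went": "go", "gone": "go",
}
_IRREGULAR_NOUNS = {
    "children": "child", "men": "man", "women": "woman",
    "feet": "foot", "teeth": "tooth", "mice": "mouse",
}

SuffixRules = Mapping[str, Sequence[tuple[str, str]]]


@lru_cache(maxsize=None)
def default_suffix_rules() -> SuffixRules:
    rules: dict[str, list[tuple[str, str]]] = {"noun": [], "verb": []}
    for row in tsv_rows("suffix_rules.tsv"):
        pos_class, suffix = row[0], row[1]
        repl = row[2] if len(row) > 2 else ""
        rules[pos_class].append((suffix, repl))
    return {k: tuple(v) for k, v in rules.items()}


@lru_cache(maxsize=None)
def _restore_e() -> frozenset[str]:
    return word_set("restore_e.txt")


def _pos_class(pos_tag: str) -> Optional[str]:
    if pos_tag.startswith("NN"):
        return "noun"
    if pos_tag.startswith("VB") or pos_tag == "MD":
        return "verb"
    return None


def lemmatize(surface: str, pos_tag: str = "", rules: Optional[SuffixRules] = None) -> str:
    """Lowercase root of ``surface`` via ordered suffix-strip rules for its POS class.

    Unknown patterns (and POS classes other than noun/verb) return the
    lowercased surface unchanged; the function is idempotent.
    """
    if not surface:
        raise ValueError("surface must be non-empty")
    w = surface.lower()
    cls = _pos_class(pos_tag or "")
    if cls is None:
        return w
    if cls == "verb" and w in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[w]
    if cls == "noun" and w in _IRREGULAR_NOUNS:
        return _IRREGULAR_NOUNS[w]
    if rules is None:
        rules = default_suffix_rules()
    for suffix, repl in rules.get(cls, ()):
        if not w.endswith(suffix):
            continue
        stem = w[: len(w) - len(suffix)] + repl
        if len(stem) < 2:
            continue
        if repl == "" and suffix in ("ing", "ed"):
            if stem in _restore_e():
                stem += "e"
            elif (
                len(stem) >= 3
                and stem[-1] == stem[-2]
                and stem[-1] not in "aeiousl"
            ):
                stem = stem[:-1]
        return stem
    return w


def annotate_lemmas(sentence: SentenceRec, rules: Optional[SuffixRules] = None) -> SentenceRec:
    """Fill the lemma field of every word/number token."""
    toks = []
    for tok in sentence.tokens:
        if tok.kind is TokenKind.WORD:
            toks.append(replace(tok, lemma=lemmatize(tok.surface, tok.pos_tag or "", rules)))
        elif tok.kind is TokenKind.NUMBER:
            toks.append(replace(tok, lemma=tok.surface))
        else:
            toks.append(tok)
    return replace(sentence, tokens=tuple(toks))


def preprocess_text(
    text: str,
    source_id: str = "",
    tagger: Optional[RuleTagger] = None,
    abbreviations: Optional[Iterable[str]] = None,
    rules: Optional[SuffixRules] = None,
) -> list[SentenceRec]:
    """Tokenize (compact), split, tag and lemmatize ``text``."""
    tokens = tokenize(text, mode="compact")
    out = []
    for sent in split_sentences(tokens, abbreviations, source_id=source_id):
        out.append(annotate_lemmas(pos_tag(sent, tagger), rules))
    return out
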