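"""Noun-phrase / verb-phrase chunking and phrase-feature cleanup.

The default backend is a deterministic rule chunker over Penn Treebank tags:

* NP: an optional leading adverb (only when it modifies a following
  determiner/number/adjective, as in "Only two protein subunits"), then a run
  of DT/PDT/CD/JJ* tokens, headed by at least one NN*; a coordinating
  conjunction is absorbed when both sides are nominal ("Pop1p and Pop4p",
  "efficacy and safety").
* VP: a run of MD/VB* tokens with trailing adverbs absorbed.

Other chunk classes (ADVP, PP, ...) are discarded. Chunks never cross
punctuation and are non-overlapping, in sentence order. Any drop-in backend
must reproduce the same observable chunks on the documented examples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._resources import word_set
from .exceptions import ConfigurationError
from .preprocess import SentenceRec, SuffixRules, Token, TokenKind, lemmatize


@dataclass(frozen=True)
class PhraseChunk:
    """A contiguous NP or VP; ``q`` is its word-dimension count."""

    kind: str  # "NP" | "VP"
    tokens: tuple[Token, ...]
    sentence_ref: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("NP", "VP"):
            raise ValueError(f"chunk kind must be NP or VP, got {self.kind!r}")
        if self.q < 1:
            raise ValueError("a phrase chunk needs at least one word token")

    @property
    def word_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.kind is TokenKind.WORD)

    @property
    def q(self) -> int:
        """Number of word dimensions (word-kind tokens) of the phrase."""
        return len(self.word_tokens)

    @property
    def text(self) -> str:
        return " ".join(t.surface for t in self.tokens)


@dataclass(frozen=True)
class PhraseFeature:
    """A cleaned phrase: lowercase, lemmatized, free of stopwords and punctuation."""

    text: str
    kind: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("phrase feature text must be non-empty")


def default_stopwords() -> frozenset[str]:
    return word_set("stopwords.txt")


_NP_PRE = frozenset({"DT", "PDT", "CD", "JJ", "JJR", "JJS"})


def _is_nominal(tag: str) -> bool:
    return tag.startswith("NN")


def _is_verbal(tag: str) -> bool:
    return tag.startswith("VB") or tag == "MD"


class RuleChunker:
    """Deterministic NP/VP chunker over Penn tags (grammar in the module docstring)."""

    def chunk(self, sentence: SentenceRec) -> list[PhraseChunk]:
        chunks: list[PhraseChunk] = []
        for segment in self._segments(sentence):
            chunks.extend(self._chunk_segment(segment, sentence.source_id))
        return chunks

    @staticmethod
    def _segments(sentence: SentenceRec) -> list[list[Token]]:
        """Maximal word/number runs; punctuation breaks a run, spaces do not."""
        segs: list[list[Token]] = []
        cur: list[Token] = []
        for tok in sentence.tokens:
            if tok.kind in (TokenKind.WORD, TokenKind.NUMBER):
                cur.append(tok)
            elif tok.kind is TokenKind.PUNCTUATION:
                if cur:
                    segs.append(cur)
                cur = []
        if cur:
            segs.append(cur)
        return segs

    def _chunk_segment(self, toks: list[Token], ref: str) -> list[PhraseChunk]:
        tags = [t.pos_tag or "" for t in toks]
        n = len(toks)
        out: list[PhraseChunk] = []
        i = 0
        while i < n:
            tag = tags[i]
            if _is_verbal(tag):
                j = i + 1
                while j < n and _is_verbal(tags[j]):
                    j += 1
                while j < n and tags[j] == "RB":  # trailing adverbs
                    j += 1
                out.append(PhraseChunk("VP", tuple(toks[i:j]), ref))
                i = j
                continue
            end = self._consume_np(tags, i)
            if end is not None:
                out.append(PhraseChunk("NP", tuple(toks[i:end]), ref))
                i = end
            else:
                i += 1
        return out

    @staticmethod
    def _consume_np(tags: list[str], i: int) -> Optional[int]:
        n = len(tags)
        j = i
        if tags[j] == "RB":
            if j + 1 < n and tags[j + 1] in _NP_PRE:
                j += 1
            else:
                return None
        if not (tags[j] in _NP_PRE or _is_nominal(tags[j])):
            return None
        has_head = False
        while j < n:
            if tags[j] in _NP_PRE or _is_nominal(tags[j]):
                has_head = has_head or _is_nominal(tags[j])
                j += 1
                continue
            if tags[j] == "CC" and has_head:
                # absorb coordination only when the right side is nominal too
                k = j + 1
                right_head = False
                while k < n and (tags[k] in _NP_PRE or _is_nominal(tags[k])):
                    right_head = right_head or _is_nominal(tags[k])
                    k += 1
                if right_head:
                    j = k
                    continue
            break
        return j if has_head and j > i else None


_DEFAULT_CHUNKER: Optional[RuleChunker] = None


def get_chunker(backend: str = "rule") -> RuleChunker:
    global _DEFAULT_CHUNKER
    if backend == "rule":
        if _DEFAULT_CHUNKER is None:
            _DEFAULT_CHUNKER = RuleChunker()
        return _DEFAULT_CHUNKER
    raise ConfigurationError(
        f"chunker backend {backend!r} is not available; configure 'rule' "
        "or register a backend object implementing chunk(sentence)"
    )


def chunk_sentence(sentence: SentenceRec, chunker: Optional[RuleChunker] = None) -> list[PhraseChunk]:
    """Extract NP and VP chunks from a POS-tagged sentence."""
    untagged = [t for t in sentence.word_tokens if t.pos_tag is None]
    if untagged:
        raise ValueError(
            f"sentence {sentence.source_id!r} is not POS-tagged "
            f"(first untagged token: {untagged[0].surface!r})"
        )
    if chunker is None:
        chunker = get_chunker()
    return chunker.chunk(sentence)


def phrase_to_feature(
    chunk: PhraseChunk,
    stopwords: Optional[frozenset[str]] = None,
    rules: Optional[SuffixRules] = None,
) -> Optional[PhraseFeature]:
    """Lowercase/lemmatize the chunk's words, drop stopwords and punctuation.

    Returns None when no word survives.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    words: list[str] = []
    for tok in chunk.tokens:
        if tok.kind is TokenKind.PUNCTUATION or tok.kind is TokenKind.SPACE:
            continue
        if tok.kind is TokenKind.NUMBER:
            words.append(tok.surface)
            continue
        lemma = tok.lemma or lemmatize(tok.surface, tok.pos_tag or "", rules)
        if lemma in stopwords or tok.surface.lower() in stopwords:
            continue
        words.append(lemma)
    if not words:
        return None
    return PhraseFeature(text=" ".join(words), kind=chunk.kind)
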