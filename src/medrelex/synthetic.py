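"""Synthetic labeled corpora and matching concept lexica.

The generator emulates the shape of a disease-treatment sentence corpus:
each class emits sentences from a fixed POS-taggable template,

    the <subject NP> <verb> the <object NP> [with <noise words>] .

where class-discriminative cue phrases (a verb for VP cues, a multiword
noun phrase for NP cues) are substituted with a configurable emission
probability, subjects/objects are drawn from a shared noun pool, and noise
words come from a shared pseudo-word vocabulary. The matching lexicon
generator gives cue words/phrases high-scoring entries (default scores
700-1000, allow-listed semantic types) with a configurable coverage
probability, and noise/filler words sub-threshold entries (scores 0-599), so
that concept-ranking behavior is controllable end to end. All randomness
flows from the config seed through named generators; a fixed seed yields
byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .concept_ranking import DEFAULT_ALLOWED_TYPES
from .io import CorpusRecord

SHARED_NOUNS = (
    "patient",
    "therapy",
    "infection",
    "symptom",
    "dose",
    "cohort",
    "regimen",
    "lesion",
    "marker",
    "biopsy",
)

NEUTRAL_VERB = "affects"


@dataclass(frozen=True)
class CueSpec:
    """A class-discriminative cue: a verb ('vp') or a noun phrase ('np')."""

    kind: str  # "np" | "vp"
    text: str
    prob: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("np", "vp"):
            raise ValueError(f"cue kind must be 'np' or 'vp', got {self.kind!r}")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"cue probability must be in [0, 1], got {self.prob}")


@dataclass(frozen=True)
class ClassSpec:
    label: str
    n: int
    cues: tuple[CueSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("each class needs n >= 1 sentences")


@dataclass(frozen=True)
class SynthConfig:
    classes: tuple[ClassSpec, ...]
    shared_noise_vocab_size: int = 30
    noise_terms_per_sentence: tuple[int, int] = (0, 0)
    sentence_length: tuple[int, int] = (0, 0)  # extra shared filler nouns
    seed: int = 42


@dataclass(frozen=True)
class SynthLexiconConfig:
    coverage_probability: float = 1.0
    score_range_cue: tuple[int, int] = (700, 1000)
    score_range_noise: tuple[int, int] = (0, 599)
    semantic_type_pool: tuple[str, ...] = tuple(sorted(DEFAULT_ALLOWED_TYPES))
    noise_entry_probability: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_probability <= 1.0:
            raise ValueError("coverage_probability must be in [0, 1]")
        for rng_name in ("score_range_cue", "score_range_noise"):
            lo, hi = getattr(self, rng_name)
            if not (0 <= lo <= hi <= 1000):
                raise ValueError(f"{rng_name} must be within [0, 1000]")


def _pseudowords(rng: np.random.Generator, count: int) -> list[str]:
    """Deterministic pronounceable pseudo-words, distinct from the shared nouns."""
    consonants = "bdfgklmnprstvz"
    vowels = "aeiou"
    out: list[str] = []
    seen = set(SHARED_NOUNS)
    while len(out) < count:
        syllables = int(rng.integers(2, 4))
        word = "".join(
            consonants[int(rng.integers(len(consonants)))]
            + vowels[int(rng.integers(len(vowels)))]
            for _ in range(syllables)
        )
        if word not in seen:
            seen.add(word)
            out.append(word)
    return out


def noise_vocabulary(config: SynthConfig) -> list[str]:
    rng = np.random.default_rng(config.seed + 1)
    return _pseudowords(rng, config.shared_noise_vocab_size)


def generate_corpus(config: SynthConfig) -> list[CorpusRecord]:
    """Render the labeled synthetic corpus; deterministic under the config seed."""
    rng = np.random.default_rng(config.seed)
    vocab = noise_vocabulary(config)
    lo_n, hi_n = config.noise_terms_per_sentence
    lo_f, hi_f = config.sentence_length
    if lo_n > hi_n or lo_f > hi_f:
        raise ValueError("range fields must be (low, high) with low <= high")
    records: list[CorpusRecord] = []
    for cls in config.classes:
        for i in range(cls.n):
            subject = str(rng.choice(SHARED_NOUNS))
            obj = str(rng.choice(SHARED_NOUNS))
            verb = NEUTRAL_VERB
            np_cues_used = 0
            for cue in cls.cues:
                if rng.random() >= cue.prob:
                    continue
                if cue.kind == "vp":
                    verb = cue.text
                elif np_cues_used == 0:
                    obj = cue.text
                    np_cues_used += 1
                else:
                    subject = cue.text
            words = ["the", subject, verb, "the", obj]
            n_filler = int(rng.integers(lo_f, hi_f + 1)) if hi_f else 0
            for _ in range(n_filler):
                words.append(str(rng.choice(SHARED_NOUNS)))
            n_noise = int(rng.integers(lo_n, hi_n + 1)) if hi_n else 0
            if n_noise:
                words.append("with")
                picks = rng.choice(len(vocab), size=n_noise, replace=True)
                words.extend(vocab[int(p)] for p in picks)
            text = " ".join(words) + "."
            records.append(
                CorpusRecord(label=cls.label, text=text, id=f"{cls.label}-{i}")
            )
    return records


def _cue_terms(config: SynthConfig) -> list[str]:
    """Unique cue words and full cue-phrase strings, in config order."""
    seen: list[str] = []
    for cls in config.classes:
        for cue in cls.cues:
            terms = cue.text.split()
            if len(terms) > 1:
                terms = terms + [cue.text]
            for t in terms:
                if t not in seen:
                    seen.append(t)
    return seen


def generate_lexicon(
    corpus_config: SynthConfig,
    config: Optional[SynthLexiconConfig] = None,
    seed: Optional[int] = None,
) -> dict[str, list[dict]]:
    """Concept lexicon matched to the corpus config's cue and noise terms.

    Cue words and phrases get entries scored in ``score_range_cue`` with
    allow-listed types, each with probability ``coverage_probability``; noise
    and filler words get sub-threshold entries (or none).
    """
    if config is None:
        config = SynthLexiconConfig()
    if seed is None:
        seed = corpus_config.seed + 2
    rng = np.random.default_rng(seed)
    pool = config.semantic_type_pool
    lexicon: dict[str, list[dict]] = {}

    def score(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    for term in _cue_terms(corpus_config):
        if rng.random() < config.coverage_probability:
            lo, hi = config.score_range_cue
            lexicon[term] = [
                {
                    "concept": f"{term} concept",
                    "score": score(lo, hi),
                    "types": [pool[int(rng.integers(len(pool)))]],
                }
            ]
    for term in list(SHARED_NOUNS) + noise_vocabulary(corpus_config):
        if term in lexicon:
            continue
        if rng.random() < config.noise_entry_probability:
            lo, hi = config.score_range_noise
            lexicon[term] = [
                {
                    "concept": f"{term} concept",
                    "score": score(lo, hi),
                    "types": [pool[int(rng.integers(len(pool)))]],
                }
            ]
    return lexicon


def default_corpus_config(
    seed: int = 42,
    n_per_class: int = 100,
    cue_prob: float = 1.0,
    noise_max: int = 0,
) -> SynthConfig:
    """The study-condition corpus: six labeled classes, one VP and one NP cue each."""
    cue_table = {
        "Cure": ("cures", "curative remedy"),
        "Prevent": ("prevents", "preventive vaccine"),
        "SideEffect": ("aggravates", "adverse reaction"),
        "DisOnly": ("persists", "chronic disorder"),
        "TreatOnly": ("continues", "novel intervention"),
        "Vague": ("correlates", "possible association"),
    }
    classes = tuple(
        ClassSpec(
            label=label,
            n=n_per_class,
            cues=(
                CueSpec("vp", verb, cue_prob),
                CueSpec("np", noun_phrase, cue_prob),
            ),
        )
        for label, (verb, noun_phrase) in cue_table.items()
    )
    return SynthConfig(
        classes=classes,
        noise_terms_per_sentence=(0, noise_max) if noise_max else (0, 0),
        seed=seed,
    )


def phrase_signal_config(seed: int = 42, n_per_class: int = 30) -> SynthConfig:
    """A design whose signal lives only in multiword phrases.

    Both classes contain exactly the same unigrams ("alpha", "beta", shared
    template words); they differ only in the order of the two cue words
    inside the object noun phrase, so bag-of-words features carry no class
    information while phrase-level features separate the classes.
    """
    classes = (
        ClassSpec("Cure", n_per_class, (CueSpec("np", "alpha beta", 1.0),)),
        ClassSpec("Vague", n_per_class, (CueSpec("np", "beta alpha", 1.0),)),
    )
    return SynthConfig(classes=classes, seed=seed)
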