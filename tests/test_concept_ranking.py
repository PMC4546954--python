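"""Concept-ranking filters: worked example, brute-force oracle, monotonicity."""
import numpy as np
import pytest

import medrelex as m
from medrelex.concept_ranking import DEFAULT_ALLOWED_TYPES
from medrelex.exceptions import IntegrityError

from conftest import np_chunk


def candidate(name, score, types=("Qualitative Concept",), matched=frozenset()):
    return m.ConceptCandidate(
        concept_name=name, score=score,
        semantic_types=tuple(types), matched_words=frozenset(matched),
    )


class TestMapPhrase:
    def test_worked_example_candidates(self, worked_example_lexicon):
        chunk = np_chunk("efficacy and safety")
        cands = m.map_phrase(chunk, worked_example_lexicon)
        by_name = {c.concept_name: c for c in cands}
        assert by_name["effectiveness"].score == 1000
        assert by_name["effectiveness"].semantic_types == ("Qualitative Concept",)
        assert by_name["effectiveness"].matched_words == frozenset({0})
        assert by_name["safety"].score == 1000
        assert by_name["safety"].semantic_types == ("Human-caused Phenomenon or Process",)
        assert by_name["safety"].matched_words == frozenset({2})

    def test_unknown_phrase_empty(self, worked_example_lexicon):
        assert m.map_phrase(np_chunk("unrelated words"), worked_example_lexicon) == []

    def test_single_word_direct_lookup(self):
        lex = m.load_lexicon({"efficacy": [
            {"concept": "a", "score": 700, "types": ["Activity"]},
            {"concept": "b", "score": 800, "types": ["Activity"]},
        ]})
        cands = m.map_phrase(np_chunk("efficacy"), lex)
        assert [(c.concept_name, c.score) for c in cands] == [("b", 800), ("a", 700)]
        assert all(c.matched_words == frozenset({0}) for c in cands)

    def test_deterministic_order_score_then_name(self):
        lex = m.load_lexicon({"dose": [
            {"concept": "z", "score": 900, "types": ["Activity"]},
            {"concept": "a", "score": 900, "types": ["Activity"]},
        ]})
        cands = m.map_phrase(np_chunk("dose"), lex)
        assert [c.concept_name for c in cands] == ["a", "z"]


class TestApplyFilters:
    def test_worked_example_coverage_passes(self, worked_example_lexicon):
        chunk = np_chunk("efficacy and safety")
        cands = m.map_phrase(chunk, worked_example_lexicon)
        survivors = m.apply_filters(chunk, cands)
        assert len(survivors) == 4  # two concepts per mapped word
        covered = set()
        for c in survivors:
            covered |= c.matched_words
        assert covered == {0, 2}
        assert len(covered) == chunk.q - 1

    def test_score_boundary_is_strict(self):
        chunk = np_chunk("dose")
        below = [candidate("x", 599, matched={0})]
        at = [candidate("x", 600, matched={0})]
        assert m.apply_filters(chunk, below) == []
        assert len(m.apply_filters(chunk, at)) == 1

    def test_vp_uses_vp_threshold(self):
        sent = m.preprocess_text("binds")[0]
        chunk = m.PhraseChunk(kind="VP", tokens=sent.word_tokens)
        assert m.apply_filters(chunk, [candidate("x", 650, matched={0})]) == []
        assert len(m.apply_filters(chunk, [candidate("x", 700, matched={0})])) == 1

    def test_insufficient_coverage_empties_output(self):
        chunk = np_chunk("alpha beta gamma")
        cands = [candidate("x", 1000, matched={1})]
        assert m.apply_filters(chunk, cands) == []

    def test_semantic_type_allowlist(self):
        chunk = np_chunk("dose")
        odd = [candidate("x", 900, types=("Geographic Area",), matched={0})]
        assert m.apply_filters(chunk, odd) == []
        empty_allowlist = m.RankerConfig(allowed_semantic_types=frozenset())
        assert len(m.apply_filters(chunk, odd, empty_allowlist)) == 1

    def test_out_of_range_matched_words_rejected(self):
        chunk = np_chunk("dose")
        with pytest.raises(IntegrityError):
            m.apply_filters(chunk, [candidate("x", 900, matched={3})])


class TestSelectTopConcept:
    def test_max_score_wins(self):
        a, b = candidate("a", 800, matched={0}), candidate("b", 900, matched={0})
        assert m.select_top_concept([a, b]).concept_name == "b"

    def test_empty_gives_none(self):
        assert m.select_top_concept([]) is None

    def test_tie_breaks_lexicographically(self):
        b, a = candidate("b", 900, matched={0}), candidate("a", 900, matched={0})
        assert m.select_top_concept([b, a]).concept_name == "a"


class TestRankPhrases:
    def test_worked_example_phrase_selected(self, worked_example_lexicon):
        chunk = np_chunk("efficacy and safety")
        ranked = m.rank_phrases([chunk], worked_example_lexicon)
        assert len(ranked) == 1
        assert ranked[0].phrase.text == "efficacy safety"  # 'and' is a stopword
        assert ranked[0].concept.score == 1000

    def test_unknown_chunks_yield_nothing(self, worked_example_lexicon):
        chunks = [np_chunk("random words"), np_chunk("more noise")]
        assert m.rank_phrases(chunks, worked_example_lexicon) == []

    def test_mixed_list_only_survivor_emitted(self):
        lex = m.load_lexicon({"binds": [
            {"concept": "binding", "score": 800, "types": ["Functional Concept"]},
        ]})
        sent = m.preprocess_text("binds")[0]
        vp = m.PhraseChunk(kind="VP", tokens=sent.word_tokens)
        chunks = [np_chunk("unknown stuff"), vp]
        ranked = m.rank_phrases(chunks, lex)
        assert [(r.phrase.kind, r.phrase.text) for r in ranked] == [("VP", "bind")]


# --- independent oracle and fuzzed properties --------------------------------

def brute_force_filters(q, kind, candidates, config):
    """Literal restatement of the three filter criteria, candidate by candidate."""
    thr = config.np_threshold if kind == "NP" else config.vp_threshold
    survivors = []
    for c in candidates:
        passes_score = c.score >= thr
        passes_type = (
            len(config.allowed_semantic_types) == 0
            or any(t in config.allowed_semantic_types for t in c.semantic_types)
        )
        if passes_score and passes_type:
            survivors.append(c)
    matched_dimensions = 0
    for dim in range(q):
        if any(dim in c.matched_words for c in survivors):
            matched_dimensions += 1
    if matched_dimensions >= q - 1:
        return survivors
    return []


TYPE_POOL = sorted(DEFAULT_ALLOWED_TYPES)[:4] + ["Geographic Area", "Plant"]


def random_case(rng):
    q = int(rng.integers(1, 5))
    words = " ".join(f"w{i}" for i in range(q))
    chunk = np_chunk(words) if rng.random() < 0.5 else m.PhraseChunk(
        kind="VP", tokens=m.preprocess_text(words)[0].word_tokens
    )
    n_cand = int(rng.integers(0, 7))
    cands = []
    for i in range(n_cand):
        matched = {int(d) for d in rng.choice(q, size=int(rng.integers(1, q + 1)),
                                              replace=False)}
        types = tuple(
            rng.choice(TYPE_POOL, size=int(rng.integers(1, 3)), replace=False)
        )
        cands.append(candidate(f"c{i}", int(rng.integers(0, 1001)),
                               types=types, matched=matched))
    return chunk, cands


def test_filter_oracle_equivalence_on_random_phrases():
    rng = np.random.default_rng(7)
    config = m.RankerConfig()
    for _ in range(500):
        chunk, cands = random_case(rng)
        got = m.apply_filters(chunk, cands, config)
        expected = brute_force_filters(chunk.q, chunk.kind, cands, config)
        assert {c.concept_name for c in got} == {c.concept_name for c in expected}


def test_threshold_monotonicity_over_random_lexica():
    """Raising either threshold never enlarges the set of ranked concepts."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        chunks, cands_list = [], []
        for _ in range(4):
            chunk, cands = random_case(rng)
            chunks.append(chunk)
            cands_list.append(cands)

        def ranked_keys(np_thr, vp_thr):
            cfg = m.RankerConfig(np_threshold=np_thr, vp_threshold=vp_thr)
            keys = set()
            for i, (chunk, cands) in enumerate(zip(chunks, cands_list)):
                top = m.select_top_concept(m.apply_filters(chunk, cands, cfg), cfg)
                if top is not None:
                    keys.add(i)
            return keys

        loose = ranked_keys(400, 500)
        mid = ranked_keys(600, 700)
        tight = ranked_keys(800, 900)
        assert tight <= mid <= loose


def test_rank_phrases_deterministic(worked_example_lexicon):
    chunks = [np_chunk("efficacy and safety"), np_chunk("safety")]
    a = m.rank_phrases(chunks, worked_example_lexicon)
    b = m.rank_phrases(chunks, worked_example_lexicon)
    assert a == b


def test_top_concept_score_is_max_over_survivors():
    rng = np.random.default_rng(3)
    for _ in range(50):
        chunk, cands = random_case(rng)
        survivors = m.apply_filters(chunk, cands, m.RankerConfig())
        top = m.select_top_concept(survivors)
        if survivors:
            assert top.score == max(c.score for c in survivors)
        else:
            assert top is None
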