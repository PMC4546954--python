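import json

import pytest

import medrelex as m
from medrelex._resources import data_text


@pytest.fixture(scope="session")
def worked_example_lexicon():
    """The mapping-output fixture for 'efficacy'/'safety' (no entry for 'and')."""
    return m.load_lexicon(json.loads(data_text("worked_example_lexicon.json")))


@pytest.fixture(scope="session")
def example_sentence():
    """The chunking example sentence, preprocessed with the default backends."""
    text = "Only two protein subunits, Pop1p and Pop4p, specifically bind the RNA subunit."
    sents = m.preprocess_text(text, source_id="ex")
    assert len(sents) == 1
    return sents[0]


def np_chunk(text: str) -> m.PhraseChunk:
    """Build an NP chunk from raw text via the default pipeline."""
    sent = m.preprocess_text(text)[0]
    return m.PhraseChunk(kind="NP", tokens=sent.word_tokens)
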