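import numpy as np
import pandas as pd
import pytest

from schwalearn.synthetic import (CorpusToken, LanguageConfig, LexiconEntry,
                                  build_lexicon, corpus_to_frame,
                                  default_ground_truth,
                                  generate_formant_tracks, sample_corpus)


def make_token(token_id, utterance_id, position, form, phones, word_class,
               functions=(), speaker="spk00", duration=None, rate=5.5):
    entry = LexiconEntry(form=form, phones=tuple(phones),
                         word_class=word_class,
                         functions=frozenset(functions),
                         schwa_final=tuple(phones)[-1] == "5")
    return CorpusToken(token_id=token_id, utterance_id=utterance_id,
                       position=position, speaker_id=speaker, entry=entry,
                       vowel_duration=duration, local_speaking_rate=rate,
                       n_segments=len(phones))


@pytest.fixture
def example_sentence():
    """The worked five-word window: 'das ist dieser grosse mann', with the
    demonstrative-pronoun target 'dieser' in the centre."""
    return [
        make_token("t0", 0, 0, "das", "das", "other"),
        make_token("t1", 0, 1, "ist", ["I", "s", "t"], "other"),
        make_token("t2", 0, 2, "dieser", ["d", "i", "z", "5"],
                   "complex_function",
                   functions=("Demonstrativpronomen", "Maskulin", "Nominativ"),
                   duration=0.05),
        make_token("t3", 0, 3, "große", ["g", "r", "o", "s", "@"], "other"),
        make_token("t4", 0, 4, "mann", "man", "other"),
    ]


@pytest.fixture(scope="session")
def small_language():
    """A small but complete synthetic corpus shared across tests."""
    config = LanguageConfig(n_word_types=80, n_tokens=1500, n_speakers=4,
                            seed=7)
    lexicon = build_lexicon(config)
    corpus = sample_corpus(lexicon, config)
    return config, lexicon, corpus


@pytest.fixture(scope="session")
def small_tracks(small_language):
    config, _, corpus = small_language
    schwa = [t for t in corpus if t.entry.schwa_final]
    truth = default_ground_truth(config)
    tracks = generate_formant_tracks(schwa, truth, config)
    return schwa, truth, tracks


@pytest.fixture(scope="session")
def token_info(small_tracks):
    schwa, _, _ = small_tracks
    frame = corpus_to_frame(schwa)[["token_id", "word_class",
                                    "vowel_duration_s"]].copy()
    frame["vowel_duration_s"] = frame["vowel_duration_s"].astype(float)
    return frame
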