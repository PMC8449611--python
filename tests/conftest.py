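import pytest

from ohcmine.corpus_io import GeneratorConfig, generate_synthetic_corpus
from ohcmine.offlabel import load_label_map
from ohcmine.spellnorm import Lexicon, LexiconEntry, bundled_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def label_map():
    return load_label_map()


@pytest.fixture(scope="session")
def tiny_lexicon():
    """Hand-sized lexicon for crafted examples."""
    entries = [
        LexiconEntry("gabapentin", "gabapentin", "drug"),
        LexiconEntry("quetiapine", "quetiapine", "drug"),
        LexiconEntry("lorazepam", "lorazepam", "drug"),
        LexiconEntry("pain", "pain", "indication"),
        LexiconEntry("nerve pain", "neuropathic_pain", "indication"),
        LexiconEntry("insomnia", "sleep_disorder_insomnia", "indication"),
        LexiconEntry("anxiety", "anxiety", "indication"),
    ]
    vocab = {
        "i", "take", "for", "my", "doctor", "prescribed", "works", "it",
        "the", "was", "given", "not", "and", "really", "helps", "pains",
    }
    return Lexicon(entries=entries, general_vocabulary=vocab)


@pytest.fixture(scope="session")
def small_corpus(lexicon, label_map):
    """A 300-post seeded corpus shared across tests."""
    cfg = GeneratorConfig(n_posts=300, seed=11)
    return generate_synthetic_corpus(cfg, lexicon, label_map)
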