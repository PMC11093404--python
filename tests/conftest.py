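import pytest

from agreesim.corpus import (
    GrammarConfig, Grammar, generate_corpus, build_vocab, TAGSET,
)
from agreesim.neural_lm import EncoderConfig, TrainConfig, LanguageModel, train


@pytest.fixture(scope="session")
def grammar_config():
    return GrammarConfig(seed=7)


@pytest.fixture(scope="session")
def grammar(grammar_config):
    return Grammar(grammar_config)


@pytest.fixture(scope="session")
def small_corpus(grammar_config):
    # boosted construction rates so a short corpus still contains RCs etc.
    cfg = GrammarConfig(seed=7, p_pp_modifier=0.2, p_rc_modifier=0.1,
                        p_nested_pp=0.03, p_disjunct_subject=0.02)
    return generate_corpus(cfg, 3000)


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return build_vocab(small_corpus)


@pytest.fixture(scope="session")
def trained_models(small_corpus, small_vocab):
    """One briefly trained LM-only and one multitask model on a small corpus;
    shared by simulation and probing tests."""
    enc = EncoderConfig("lstm", 2, 32, 32)
    train_c, held = small_corpus[:2700], small_corpus[2700:]
    lm, _ = train(LanguageModel(small_vocab, enc, seed=0),
                  train_c, TrainConfig(epochs=10, seed=0, weight_word=1.0, weight_tag=0.0,
                                       batch_size=32))
    mt, _ = train(LanguageModel(small_vocab, enc, tagset=list(TAGSET), seed=1),
                  train_c, TrainConfig(epochs=10, seed=1, batch_size=32))
    return {"lm_only": lm, "multitask": mt, "held": held, "train": train_c}
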