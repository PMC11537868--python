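import numpy as np
import pytest

from ablm.abcore import AnnotatedChain, RegionAnnotation
from ablm.synth import GrammarConfig, build_grammar, sample_corpus, sample_heavy

#: reduced grammar used wherever a corpus is needed: same structure, shorter
#: frameworks so attention (O(N^2)) stays cheap on one CPU
MINI_GRAMMAR = GrammarConfig(
    fr_lengths=(12, 8, 16, 6),
    light_fr_lengths=(10, 7, 14, 5),
    cdr12_length=6,
    light_cdr12_length=5,
    cdr3_len_range=(8, 14),
    light_cdr3_length=8,
    seed=11,
)


@pytest.fixture(scope="session")
def grammar():
    return build_grammar(MINI_GRAMMAR)


@pytest.fixture(scope="session")
def full_grammar():
    return build_grammar(GrammarConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def heavy_chains(grammar):
    rng = np.random.default_rng(100)
    return [sample_heavy(grammar, rng, uid=f"T{i:04d}") for i in range(40)]


def make_chain(seq: str, lengths=None, chain_type="heavy", cid="c1") -> AnnotatedChain:
    regions = RegionAnnotation.from_lengths(lengths) if lengths else None
    return AnnotatedChain(cid, chain_type, seq, regions)


@pytest.fixture(scope="session")
def desk_encoder(grammar):
    """Encoder pretrained on the reduced grammar; shared by evaluation and
    head tests (train once per session, ~3 min)."""
    from ablm.encoder import EncoderConfig
    from ablm.masking import MaskingConfig
    from ablm.pretrain import TrainConfig, train_mlm

    rng = np.random.default_rng(1)
    corpus = sample_corpus(grammar, 1200, 300, rng)
    encoder, metrics = train_mlm(
        corpus,
        MaskingConfig(),
        EncoderConfig(),
        TrainConfig(epochs=24, warmup_epochs=2, batch_size=32, seed=0, base_lr=3e-3),
    )
    return encoder
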