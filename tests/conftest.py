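import pytest

from grgt.depgraph import LabelHierarchy
from grgt.lexicon import default_lexicon
from grgt.synthdata import GeneratorConfig, builtin_fixtures, generate_corpus


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def hierarchy():
    return LabelHierarchy()


@pytest.fixture(scope="session")
def fixtures_by_id():
    return {cs.sentence_id: cs for cs in builtin_fixtures()}


@pytest.fixture(scope="session")
def small_corpus(lex):
    """200-sentence noise-free synthetic corpus, fixed seed."""
    return generate_corpus(GeneratorConfig(n_sentences=200, seed=42), lex)
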