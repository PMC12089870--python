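import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from carenet.lexicon import load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """A 20-patient synthetic corpus at default noise, with its ground truth."""
    from carenet.simulate import GeneratorConfig, generate

    return generate(GeneratorConfig(n_patients=20, seed=42))
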