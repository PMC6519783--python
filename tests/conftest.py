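import io
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from suppsignal import load_effects, load_products

DATA_DIR = Path(__file__).parent / "data"

# The validation anecdote: a paragraph discussing creatine that also mentions
# "rpm", so every effect gets attributed to both products.
EXAMPLE_I_TEXT = (
    "Creatine geeft mij vooral meer kracht, (zo’n 10% van mijn rpm erbij) "
    "explosieve kracht, niet veel meer uithoudingsvermogen."
)

EXAMPLE_I_PRODUCTS_TSV = "RPM\tproduct\trpm\ncreatine\tproduct\t\n"

EXAMPLE_I_VOCAB_TSV = (
    "meer\tQUANT\tother\t0\t-\n"
    "kracht\tNOUN\tvague_noun\t0\t-\n"
    "explosieve\tADJ\teffect_adj\t0\t-\n"
    "uithoudingsvermogen\tNOUN\teffect_noun\t0\t-\n"
)

EXAMPLE_I_RULES_TSV = (
    "r_meer_kracht\tlit:meer+lit:kracht\t0\tmuscles\n"
    "r_expl_kracht\tlit:explosieve+lit:kracht\t0\tmuscles\n"
    "r_meer_uithou\tlit:meer+lit:uithoudingsvermogen\t0\tmuscles\n"
)


@pytest.fixture
def small_corpus_path() -> Path:
    return DATA_DIR / "corpus_small.xml"


@pytest.fixture
def raw_corpus_path() -> Path:
    return DATA_DIR / "raw_small.xml"


@pytest.fixture
def example_i_products():
    return load_products(io.StringIO(EXAMPLE_I_PRODUCTS_TSV))


@pytest.fixture
def example_i_lexicon():
    return load_effects(
        io.StringIO(EXAMPLE_I_VOCAB_TSV), io.StringIO(EXAMPLE_I_RULES_TSV)
    )
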