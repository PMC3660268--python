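import random
import re

import pytest
from hypothesis import HealthCheck, settings

from ptmscreen.corpus_io import Sentence, make_abstract_document
from ptmscreen.fixtures import FixtureSpec, generate_synthetic_corpus
from ptmscreen.lexicon import default_lexicon

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """150 synthetic documents, all trap classes active."""
    return generate_synthetic_corpus(FixtureSpec(n_documents=150, seed=7))


def sentence(text: str) -> Sentence:
    return Sentence(text=text, start=0, end=len(text), index=0)


def abstract(doc_id: str, title: str, body: str):
    return make_abstract_document(doc_id, title, body)


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the position-linking grammar: walk the
# tokens after a mention, collecting every maximal digit run reachable
# through linking tokens, stopping at the first non-linking token.
# ---------------------------------------------------------------------------

LINK_PUNCT = set(",;/-–()")


def oracle_rightward(text: str, mention_end: int, linking_terms) -> list:
    linking = {t.lower() for t in linking_terms}
    out = []
    for tok in re.findall(r"\d+|[A-Za-z]+|\S", text[mention_end:]):
        if tok.isdigit():
            v = int(tok)
            if 1 <= v <= 99999 and v not in out:
                out.append(v)
        elif tok.lower() in linking or tok in LINK_PUNCT:
            continue
        else:
            break
    return out


def random_chain_sentence(rng: random.Random, linking_terms):
    """Build '<prefix> <residue> <chain> <breaker tail>' with known reachable
    numbers; returns (text, mention_span, expected_positions)."""
    residue = rng.choice(["serine", "threonine", "tyrosine"])
    prefix = rng.choice(["Phosphorylation of the", "We mapped the modified",
                         "Analysis showed the"])
    link_words = [t for t in linking_terms]
    chain = []
    expected = []
    n_groups = rng.randint(0, 3)
    for _ in range(n_groups):
        for _ in range(rng.randint(1, 2)):
            chain.append(rng.choice(link_words + [",", "and"]))
        num = rng.randint(1, 500)
        chain.append(str(num))
        if num not in expected:
            expected.append(num)
    tail = rng.choice(["kinase domain", "mutant protein", "complex"])
    trailing = f" {tail} near {rng.randint(1, 99)}."
    text = f"{prefix} {residue} {' '.join(chain)}{trailing}"
    start = text.index(residue)
    return text, (start, start + len(residue)), expected
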