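import pytest

from smisym.context import apply_context, default_triggers
from smisym.corpus import Document
from smisym.lexicon import default_lexicon
from smisym.textproc import build_instances


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def verbatim_lexicon():
    return default_lexicon("table1_verbatim")


@pytest.fixture(scope="session")
def triggers():
    return default_triggers()


@pytest.fixture(scope="session")
def mk_instances(lexicon, triggers):
    """Extract context-flagged instances from a text snippet."""

    def _make(text, concept=None, doc_id="doc1"):
        out = []
        for inst in build_instances(text, doc_id, lexicon):
            inst.context = apply_context(inst, triggers)
            if concept is None or inst.concept == concept:
                out.append(inst)
        return out

    return _make


@pytest.fixture(scope="session")
def mk_instance(mk_instances):
    """Extract exactly one instance of a concept from a snippet."""

    def _make(text, concept, doc_id="doc1"):
        found = mk_instances(text, concept, doc_id)
        assert len(found) == 1, f"expected 1 {concept} instance in {text!r}, got {len(found)}"
        return found[0]

    return _make
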