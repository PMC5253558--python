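"""Segmentation, tokenization, matching, modifier windows and instances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smisym.lexicon import token_matches
from smisym.textproc import (
    MODIFIER_WINDOW,
    attach_modifiers,
    build_instances,
    match_keywords,
    segment_sentences,
)


class TestSegmentation:
    def test_two_terminated_sentences(self):
        sents = segment_sentences("He is agitated. Sleep was poor.")
        assert len(sents) == 2

    def test_no_terminal_punctuation_is_one_sentence(self):
        text = "mood objectively low with poor eye contact"
        sents = segment_sentences(text)
        assert len(sents) == 1
        assert (sents[0].start, sents[0].end) == (0, len(text))

    def test_offsets_slice_back(self):
        text = "First sentence here. Second one!\nThird line without stop"
        sents = segment_sentences(text)
        assert [text[s.start : s.end] for s in sents] == [
            "First sentence here.", "Second one!", "Third line without stop",
        ]

    def test_internal_period_does_not_split(self):
        sents = segment_sentences("Dose was 3.5 mg daily. Continue.")
        assert len(sents) == 2

    def test_empty_text(self):
        assert segment_sentences("") == []
        assert segment_sentences("   \n  ") == []

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.text(alphabet="ab .!?\n,", max_size=80))
    def test_sentences_cover_all_nonspace_text(self, text):
        sents = segment_sentences(text)
        covered = sum(len(text[s.start : s.end]) for s in sents)
        nonspace = len([c for c in text if not c.isspace()])
        # spans may include internal spaces but never surrounding whitespace
        assert covered >= nonspace
        for s in sents:
            assert not text[s.start].isspace() and not text[s.end - 1].isspace()
            for t in s.tokens:
                assert text[t.start : t.end] == t.text


class TestTokenization:
    def test_punctuation_peeled_into_tokens(self):
        (s,) = segment_sentences('He said "hello", then left.')
        assert [t.text for t in s.tokens] == [
            "He", "said", '"', "hello", '"', ",", "then", "left", ".",
        ]

    def test_hyphenated_kept_whole(self):
        (s,) = segment_sentences("He was well-kempt today")
        assert "well-kempt" in [t.text for t in s.tokens]

    def test_word_flag(self):
        (s,) = segment_sentences("agitated , and restless")
        flags = [t.is_word for t in s.tokens]
        assert flags == [True, False, True, True]


class TestKeywordMatching:
    def test_shared_keyword_yields_match_per_concept(self, lexicon):
        (s,) = segment_sentences("There was some poverty of speech and content of thought.")
        concepts = {m.concept for m in match_keywords(s, lexicon)}
        # 'speech' is a keyword of both speech concepts; 'poverty of thought'
        # is not present as a phrase
        assert "Poverty of speech" in concepts
        assert "Pressured speech" in concepts
        assert "Poverty of thought" not in concepts

    def test_good_eye_contact_and_rapport(self, lexicon):
        (s,) = segment_sentences("she presented with good eye contact and rapport.")
        concepts = {m.concept for m in match_keywords(s, lexicon)}
        assert {"Diminished eye contact", "Poor rapport"} <= concepts

    def test_excluded_concepts_never_match(self, lexicon):
        (s,) = segment_sentences("mood was low with loose associations and stereotypy.")
        concepts = {m.concept for m in match_keywords(s, lexicon)}
        assert concepts.isdisjoint({"Low mood", "Loosening of associations", "Stereotypy"})

    def test_no_lexicon_token(self, lexicon):
        (s,) = segment_sentences("the plan was reviewed with the team.")
        assert match_keywords(s, lexicon) == []


class TestModifierWindow:
    def test_adjacent_modifier_distance(self, lexicon):
        (s,) = segment_sentences("has been having auditory command hallucinations today.")
        (m,) = [k for k in match_keywords(s, lexicon) if k.concept == "Hallucinations"]
        mods = attach_modifiers(m, s, lexicon["Hallucinations"])
        assert [x.matched_text for x in mods] == ["auditory"]
        assert mods[0].distance == 1  # 'command' intervenes

    def test_window_boundary_eight_vs_nine(self, lexicon):
        concept = lexicon["Disturbed sleep"]
        # exactly 8 intervening word tokens -> attached
        text8 = "sleep has over the past two weeks been badly disturbed."
        (s,) = segment_sentences(text8)
        (kw,) = [k for k in match_keywords(s, lexicon) if k.concept == "Disturbed sleep"]
        assert [m.matched_text for m in attach_modifiers(kw, s, concept)] == ["disturbed"]
        assert attach_modifiers(kw, s, concept)[0].distance == 8
        # one more intervening word -> outside the window
        text9 = "sleep has over the very past two weeks been badly disturbed."
        (s9,) = segment_sentences(text9)
        (kw9,) = [k for k in match_keywords(s9, lexicon) if k.concept == "Disturbed sleep"]
        assert attach_modifiers(kw9, s9, concept) == []

    def test_punctuation_does_not_count(self, lexicon):
        concept = lexicon["Disturbed sleep"]
        text = "sleep , , , , disturbed."
        (s,) = segment_sentences(text)
        (kw,) = [k for k in match_keywords(s, lexicon) if k.concept == "Disturbed sleep"]
        (mod,) = attach_modifiers(kw, s, concept)
        assert mod.distance == 0


class TestBuildInstances:
    def test_mandatory_modifier_gates_instance(self, lexicon):
        insts = build_instances("Speech was pressured.", "d", lexicon)
        assert [i.concept for i in insts] == ["Pressured speech"]
        assert [m.matched_text for m in insts[0].modifiers] == ["pressured"]

    def test_ambiguous_keyword_yields_all_qualifying_concepts(self, lexicon):
        insts = build_instances("Mood was elevated.", "d", lexicon)
        # Elevated mood qualifies (mandatory modifier present); Low mood is
        # excluded from extraction entirely
        assert [i.concept for i in insts] == ["Elevated mood"]

    def test_optional_modifier_concept_without_modifier(self, lexicon):
        insts = build_instances(
            "These hallucinations are sometimes in a kind of shadow form.", "d", lexicon
        )
        (h,) = [i for i in insts if i.concept == "Hallucinations"]
        assert h.modifiers == ()

    def test_empty_document(self, lexicon):
        assert build_instances("", "d", lexicon) == []

    def test_no_instance_crosses_sentence_boundary(self, lexicon):
        text = "Thought. Block was noted. Poverty. Of speech."
        for inst in build_instances(text, "d", lexicon):
            assert inst.sentence.start <= inst.keyword.first

    def test_determinism(self, lexicon):
        text = "Mood was elevated. There was poverty of speech and paranoia."
        a = build_instances(text, "d", lexicon)
        b = build_instances(text, "d", lexicon)
        assert a == b


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence


def brute_force_instances(sentence, lexicon):
    """Enumerate every contiguous token span against every pattern, then
    apply the instance rules naively (independent of the production path)."""
    texts = [t.text.lower() for t in sentence.tokens]
    words = [t.is_word for t in sentence.tokens]
    results = set()
    for concept in lexicon.concepts:
        if concept.status == "excluded":
            continue
        spans = []
        for i in range(len(texts)):
            for j in range(i, len(texts)):
                seg = texts[i : j + 1]
                for pat in concept.keyword_patterns:
                    if len(pat) == len(seg) and all(
                        s.startswith(p[:-1]) if p.endswith("*") else s == p
                        for p, s in zip(pat, seg)
                    ):
                        spans.append((i, j))
        spans = sorted(set(spans), key=lambda x: (x[0], -(x[1] - x[0])))
        kept = []
        for a, b in spans:
            if kept and a <= kept[-1][1]:
                continue
            kept.append((a, b))
        for a, b in kept:
            mods = set()
            for i in range(len(texts)):
                for j in range(i, len(texts)):
                    seg = texts[i : j + 1]
                    for pat in concept.modifier_patterns:
                        if len(pat) == len(seg) and all(
                            s.startswith(p[:-1]) if p.endswith("*") else s == p
                            for p, s in zip(pat, seg)
                        ):
                            if j < a:
                                gap = sum(words[j + 1 : a])
                            elif i > b:
                                gap = sum(words[b + 1 : i])
                            else:
                                continue
                            if gap <= MODIFIER_WINDOW:
                                mods.add((i, j))
            if concept.modifier_mode == "mandatory" and not mods:
                continue
            results.add((sentence.start, concept.name, a, b, frozenset(mods)))
    return results


VOCAB = (
    "paranoia paranoid speech poverty impoverished pressured pressure mood elevated "
    "eye contact thought block blocking disorder ftd flight of idea ideas negative "
    "symptoms hallucinations auditory visual third person sleep poor disturbed not "
    "withdrawal social waxy mute mutism rapport affect blunted flat concrete "
    "the patient was with and a today team plan , . - review her good".split()
)


def test_oracle_equivalence_on_random_sentences(lexicon):
    """The instance finder agrees with exhaustive subsequence enumeration."""
    rng = np.random.default_rng(20_260_920)
    n_checked = 0
    for _ in range(1000):
        n_tokens = int(rng.integers(1, 31))
        words = [VOCAB[i] for i in rng.integers(0, len(VOCAB), n_tokens)]
        text = " ".join(words)
        sents = segment_sentences(text, "d")
        got = {
            (i.sentence.start, i.concept, i.keyword.first, i.keyword.last,
             frozenset((m.first, m.last) for m in i.modifiers))
            for i in build_instances(text, "d", lexicon)
        }
        want = set()
        for s in sents:
            want |= brute_force_instances(s, lexicon)
        assert got == want, f"mismatch on {text!r}"
        n_checked += 1
    assert n_checked == 1000
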