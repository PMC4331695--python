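"""Entity boundary refinement: the five modification steps."""

import random

import pytest

from chemtagger.engine import Resource, ResourceSet, annotate
from chemtagger.entities import Entity
from chemtagger.lexicon import build_lexicon
from chemtagger.normalize import SourceDocument, normalize_text
from chemtagger.postprocess import (WordLists, extend_entities, extend_entity,
                                    merge_entities, postprocess_entities,
                                    remove_stop_entities, s_transferase_rule,
                                    trim_entity)


def _entity(nt, start, end, cls="chemical", resource="lex"):
    return Entity.from_norm("D", "A", (start, end), nt,
                            entity_class=cls, resource_name=resource)


@pytest.fixture(scope="module")
def wl():
    return WordLists()


def _annotated(text, resources):
    doc = SourceDocument("D", (("A", text),))
    nts = {}
    ents = annotate(doc, resources, normalized=nts)
    return ents, nts["A"]


# ---------------------------------------------------------------------------
# step 1: extension

def test_extension_absorbs_stereo_prefix(resources, wl):
    ents, nt = _annotated("study of (S)-nornicotine in plants", resources)
    assert [e.text for e in ents] == ["nornicotine"]
    out = extend_entities(ents, nt, wl)
    assert [e.text for e in out] == ["(S)-nornicotine"]
    assert "extended" in out[0].provenance_flags


def test_hyphenated_specific_compounds_stay_separate(resources, wl):
    ents, nt = _annotated("Resorcinol-Formaldehyde resins", resources)
    out = extend_entities(ents, nt, wl)
    assert [e.text for e in out] == ["Resorcinol", "Formaldehyde"]


def test_extension_stops_at_noise_word(resources, wl):
    ents, nt = _annotated("the leucine-to-proline mutation", resources)
    out = extend_entities(ents, nt, wl)
    assert [e.text for e in out] == ["leucine", "proline"]


def test_whitespace_bounded_entity_is_fixed_point(resources, wl):
    ents, nt = _annotated("take aspirin daily", resources)
    out = extend_entities(ents, nt, wl)
    assert [e.text for e in out] == ["aspirin"]
    assert out[0].provenance_flags == frozenset()


def test_extension_never_crosses_whitespace_or_mismatched_brackets(resources, wl):
    rng = random.Random(21)
    fragments = ["aspirin", "(", ")", "-", "x", " ", "[", "]", "2"]
    for _ in range(300):
        text = "".join(rng.choice(fragments) for _ in range(rng.randint(3, 12)))
        ents, nt = _annotated(text, resources)
        for e in extend_entities(ents, nt, wl):
            s, t = e.norm_span
            assert " " not in nt.text[s:t]
            stack = []
            pairs = {")": "(", "]": "["}
            for ch in nt.text[s:t]:
                if ch in "([":
                    stack.append(ch)
                elif ch in pairs:
                    assert stack and stack[-1] == pairs[ch], (text, e.text)
                    stack.pop()
            assert not stack, (text, e.text)


def test_bracket_enclosed_entity_retries_from_outside(wl):
    nt = normalize_text("with (nornicotine)-derived compounds")
    e = _entity(nt, 6, 17)  # nornicotine inside the brackets
    out = extend_entity(e, nt, wl)
    assert out.text == "(nornicotine)-derived"


# ---------------------------------------------------------------------------
# step 2: trimming

@pytest.mark.parametrize("text,span,expected", [
    ("colloidal silver", (0, 16), "silver"),
    ("methyl group", (0, 12), "methyl"),
    ("aspirin", (0, 7), "aspirin"),
])
def test_trimming(text, span, expected, wl):
    nt = normalize_text(text)
    out = trim_entity(_entity(nt, *span), nt, wl)
    assert out.text == expected
    if expected != text:
        assert "trimmed" in out.provenance_flags


def test_trim_to_nothing_removes_entity(wl):
    nt = normalize_text("colloidal dye")
    assert trim_entity(_entity(nt, 0, 13), nt, wl) is None


# ---------------------------------------------------------------------------
# step 3: merging

def test_family_name_merge(resources, wl):
    ents, nt = _annotated("monoterpene pyridine alkaloids occur", resources)
    out = merge_entities(extend_entities(ents, nt, wl), nt, wl)
    assert [e.text for e in out] == ["monoterpene pyridine alkaloids"]
    assert "merged" in out[0].provenance_flags
    assert "+" in out[0].resource_name  # composite attribution retained


def test_instance_of_blocks_merge(resources, wl):
    ents, nt = _annotated("the genistein isoflavonoid content", resources)
    out = merge_entities(extend_entities(ents, nt, wl), nt, wl)
    assert [e.text for e in out] == ["genistein", "isoflavonoid"]


def test_single_entity_unchanged_by_merge(resources, wl):
    ents, nt = _annotated("pure aspirin sample", resources)
    assert merge_entities(ents, nt, wl) == ents


def test_overlapping_entities_merge(wl):
    nt = normalize_text("dihydroxyanthraquinone")
    a = _entity(nt, 0, 9)
    b = _entity(nt, 5, 22)
    out = merge_entities([a, b], nt, wl)
    assert [e.text for e in out] == ["dihydroxyanthraquinone"]


def test_merged_output_has_no_overlaps(resources, wl):
    rng = random.Random(5)
    words = ["monoterpene", "pyridine", "alkaloids", "aspirin", "order",
             "genistein", "isoflavonoid"]
    for _ in range(100):
        text = " ".join(rng.choice(words) for _ in range(rng.randint(2, 8)))
        ents, nt = _annotated(text, resources)
        out = merge_entities(extend_entities(ents, nt, wl), nt, wl)
        spans = sorted(e.norm_span for e in out)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


# ---------------------------------------------------------------------------
# step 4: stop-term removal

def test_gold_nanoparticles_removed(wl):
    lex = build_lexicon({"gold nanoparticles", "gold chloride"}, name="inc")
    rs = ResourceSet(resources=[Resource(name="inc", matcher=lex)])
    ents, nt = _annotated("coated gold nanoparticles here", rs)
    assert [e.text for e in ents] == ["gold nanoparticles"]
    out = remove_stop_entities(ents, nt, wl)
    assert out == []


def test_gold_chloride_kept(wl):
    lex = build_lexicon({"gold nanoparticles", "gold chloride"}, name="inc")
    rs = ResourceSet(resources=[Resource(name="inc", matcher=lex)])
    ents, nt = _annotated("add gold chloride now", rs)
    out = remove_stop_entities(ents, nt, wl)
    assert [e.text for e in out] == ["gold chloride"]


def test_stop_removal_of_empty_list(wl):
    nt = normalize_text("nothing")
    assert remove_stop_entities([], nt, wl) == []


# ---------------------------------------------------------------------------
# step 5: S-transferase special case

@pytest.mark.parametrize("text,expected", [
    ("glutathione-S-transferase activity", "glutathione-S"),
    ("glutathione S-transferase activity", "glutathione S"),
])
def test_s_transferase_rule(resources, text, expected, wl):
    ents, nt = _annotated(text, resources)
    out = s_transferase_rule(extend_entities(ents, nt, wl), nt)
    assert [e.text for e in out] == [expected]


def test_s_transferase_without_pattern_is_noop(resources, wl):
    ents, nt = _annotated("glutathione levels rose", resources)
    assert s_transferase_rule(ents, nt) == ents


# ---------------------------------------------------------------------------
# pipeline properties

def test_full_pipeline_idempotent(resources, wl):
    texts = [
        "study of (S)-nornicotine in plants",
        "monoterpene pyridine alkaloids occur",
        "the leucine-to-proline mutation",
        "glutathione-S-transferase and glutathione S-transferase",
        "Resorcinol-Formaldehyde resins",
        "the genistein isoflavonoid content",
        "aspirin with 2634-33-5 and C20H25NO6",
    ]
    for text in texts:
        ents, nt = _annotated(text, resources)
        once = postprocess_entities(ents, nt, wl)
        twice = postprocess_entities(once, nt, wl)
        assert [(e.norm_span, e.text) for e in twice] == \
            [(e.norm_span, e.text) for e in once], text


def test_modification_preserves_resource_attribution(resources, wl):
    ents, nt = _annotated("study of (S)-nornicotine in plants", resources)
    out = postprocess_entities(ents, nt, wl)
    assert out[0].resource_name == "drug"
    assert "extended" in out[0].provenance_flags
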