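"""Annotation engine: scanning, blocking, overlap resolution, attribution."""

import pytest

from chemtagger.engine import (Resource, ResourceSet, annotate,
                               apply_include_stop_lists, filter_sum_formula)
from chemtagger.entities import Entity
from chemtagger.fixtures import SUM_FORMULA_GRAMMAR
from chemtagger.grammar import compile_grammar, parse_grammar
from chemtagger.lexicon import build_lexicon
from chemtagger.normalize import SourceDocument, normalize_text


def _doc(text, doc_id="D1"):
    return SourceDocument(doc_id=doc_id, sections=(("A", text),))


def test_salt_formula_grammar_match():
    # the unrestricted formula grammar (salt/line subtypes) finds MgSO4
    formula = Resource(name="salt_formula",
                       matcher=compile_grammar(parse_grammar(SUM_FORMULA_GRAMMAR)),
                       entity_class="formula")
    rs = ResourceSet(resources=[formula])
    entities = annotate(_doc("MgSO4 dissolved"), rs)
    assert len(entities) == 1
    e = entities[0]
    assert (e.text, e.entity_class, e.resource_name) == \
        ("MgSO4", "formula", "salt_formula")


def test_sum_formula_digit_restriction_at_collection(resources):
    entities = annotate(_doc("CDK2 and C20H25NO6 and H2O"), resources)
    assert [e.text for e in entities] == ["C20H25NO6"]


def test_cas_number_annotation(resources):
    entities = annotate(_doc("stored as 2634-33-5 sample"), resources)
    assert [(e.text, e.resource_name) for e in entities] == \
        [("2634-33-5", "cas_number")]


def test_empty_document(resources):
    assert annotate(_doc(""), resources) == []


def test_blocking_lexicon_suppresses_entities():
    poly = build_lexicon({"cellulose", "polystyrene"}, name="polymer",
                         entity_class="polymer")
    blocker = build_lexicon({"cellulose"}, name="natural", role="blocking")
    rs = ResourceSet(resources=[
        Resource(name="polymer", matcher=poly, entity_class="polymer"),
        Resource(name="natural", matcher=blocker, role="blocking"),
    ])
    assert annotate(_doc("pure cellulose here"), rs) == []
    kept = annotate(_doc("pure polystyrene here"), rs)
    assert [e.text for e in kept] == ["polystyrene"]


def test_every_entity_names_exactly_one_resource(resources):
    text = "aspirin with 2634-33-5 and CID:2244 plus red phosphorus"
    names = {r.name for r in resources.resources}
    for e in annotate(_doc(text), resources):
        assert e.resource_name in names


def test_removing_a_resource_removes_its_entities(resources):
    text = "aspirin with 2634-33-5 and vancomycin"
    with_drug = annotate(_doc(text), resources)
    assert any(e.resource_name == "drug" for e in with_drug)
    without = annotate(_doc(text), resources.without("drug"))
    assert not any(e.resource_name == "drug" for e in without)


def test_no_overlapping_entities(resources):
    text = "aspirin ethane CID:123 2634-33-5 red phosphorus pig iron"
    entities = annotate(_doc(text), resources)
    spans = sorted(e.span for e in entities)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2


def test_equal_span_overlap_resolved_by_manifest_priority():
    lex_a = build_lexicon({"aspirin"}, name="first")
    lex_b = build_lexicon({"aspirin"}, name="second")
    rs = ResourceSet(resources=[
        Resource(name="first", matcher=lex_a),
        Resource(name="second", matcher=lex_b),
    ])
    entities = annotate(_doc("take aspirin now"), rs)
    assert [e.resource_name for e in entities] == ["first"]
    rs2 = ResourceSet(resources=[
        Resource(name="second", matcher=lex_b),
        Resource(name="first", matcher=lex_a),
    ])
    assert [e.resource_name for e in annotate(_doc("take aspirin now"), rs2)] \
        == ["second"]


def test_longest_span_wins_across_resources():
    short = build_lexicon({"pig"}, name="short")
    long_ = build_lexicon({"pig iron"}, name="long")
    rs = ResourceSet(resources=[
        Resource(name="short", matcher=short),
        Resource(name="long", matcher=long_),
    ])
    assert [e.text for e in annotate(_doc("pig iron ingot"), rs)] == ["pig iron"]


def test_determinism_across_document_orderings(resources):
    texts = ["aspirin and CID:22", "vancomycin with 2634-33-5"]
    docs = [_doc(t, f"D{i}") for i, t in enumerate(texts)]
    run1 = annotate(docs[0], resources) + annotate(docs[1], resources)
    run2 = list(reversed(
        annotate(docs[1], resources) + annotate(docs[0], resources)))
    assert sorted(e.sort_key() for e in run1) == \
        sorted(e.sort_key() for e in run2)


def test_correction_recovers_typo_token(resources):
    entities = annotate(_doc("patients received asp1rin daily"), resources)
    assert [e.text for e in entities] == ["asp1rin"]
    e = entities[0]
    assert e.resource_name == "drug"
    assert e.corrections  # the applied edits are recorded
    off = annotate(_doc("patients received asp1rin daily"), resources,
                   correction=False)
    assert off == []


def test_entities_report_source_coordinates(resources):
    raw = "see ‘aspirin’ today"
    doc = SourceDocument(doc_id="D1", sections=(("A", raw),))
    entities = annotate(doc, resources)
    assert len(entities) == 1
    start, end = entities[0].span
    assert raw[start:end] == "aspirin"


@pytest.mark.parametrize("text,keep", [
    ("CDK2", False),
    ("C20H25NO6", True),
    ("H2O", False),
    ("CaCo", False),
    ("HeLa", False),
])
def test_filter_sum_formula(text, keep):
    e = Entity(doc_id="D", section_label="A", span=(0, len(text)), text=text,
               entity_class="formula", resource_name="chemical_formula")
    assert filter_sum_formula(e) is keep


def test_include_list_adds_entities(resources):
    nt = normalize_text("found chikusetsusaponin L10 here")
    doc = _doc("found chikusetsusaponin L10 here")
    include = build_lexicon({"chikusetsusaponin L10"}, name="include_list")
    out = apply_include_stop_lists([], {"A": nt}, doc, include_list=include)
    assert [e.text for e in out] == ["chikusetsusaponin L10"]
    assert out[0].resource_name == "include_list"


def test_empty_lists_leave_entities_unchanged(resources):
    nt = normalize_text("aspirin here")
    doc = _doc("aspirin here")
    entities = annotate(doc, resources)
    out = apply_include_stop_lists(entities, {"A": nt}, doc)
    assert out == entities


def test_stop_list_disabled_by_default(resources):
    nt = normalize_text("aspirin here")
    doc = _doc("aspirin here")
    entities = annotate(doc, resources)
    stop = build_lexicon({"aspirin"}, name="stop_list")
    kept = apply_include_stop_lists(entities, {"A": nt}, doc, stop_list=stop,
                                    use_stop_list=False)
    assert [e.text for e in kept] == ["aspirin"]
    removed = apply_include_stop_lists(entities, {"A": nt}, doc,
                                       stop_list=stop, use_stop_list=True)
    assert removed == []
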