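"""Scanning documents against a resource set.

A :class:`ResourceSet` is an ordered collection of compiled grammars
and lexicons.  The scanner collects, at every candidate position, the
longest bracket-valid match of each resource, applies spelling
correction to uncovered tokens where a resource allows it, suppresses
anything inside a blocking-dictionary match, and resolves overlaps by
longest-span-wins (ties go to the resource listed first in the
manifest, which makes the choice auditable).  Every emitted entity
names the single resource that produced it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .correction import (NOT_APPLICABLE, CorrectionConfig, CorrectionResult,
                         EditCostModel, correct_against)
from .entities import Entity
from .grammar import CharAutomaton, Grammar, LayeredAutomaton, compile_grammar
from .lexicon import Lexicon
from .normalize import NormalizationTable, NormalizedText, SourceDocument, normalize_text

__all__ = ["Resource", "ResourceSet", "annotate", "annotate_section",
           "filter_sum_formula", "apply_include_stop_lists"]


@dataclass
class Resource:
    """One named grammar or lexicon with its scanning policy."""

    name: str
    matcher: object                      # Lexicon | CharAutomaton | LayeredAutomaton
    entity_class: str = "chemical"
    role: str = "matching"               # matching | blocking
    correction: CorrectionConfig | None = None
    is_sum_formula: bool = False

    _automaton: CharAutomaton | None = field(default=None, repr=False)
    _first_chars: set[str] | None = field(default=None, repr=False)

    @property
    def kind(self) -> str:
        return "lexicon" if isinstance(self.matcher, Lexicon) else "grammar"

    def match_longest(self, text: str, pos: int) -> tuple[int, int] | None:
        return self.matcher.match_longest(text, pos)

    def automaton(self) -> CharAutomaton:
        """The resource as a plain character DFA (the spelling-correction
        target).  Grammars already are one; lexicons are converted."""
        if self._automaton is None:
            if isinstance(self.matcher, Lexicon):
                self._automaton = self.matcher.to_automaton()
            elif isinstance(self.matcher, CharAutomaton):
                self._automaton = self.matcher
            else:
                raise TypeError(
                    f"resource {self.name!r}: no flat automaton available")
        return self._automaton

    def first_chars(self) -> set[str] | None:
        """Characters a match can start with (None = unknown, scan all)."""
        if self._first_chars is None:
            if isinstance(self.matcher, Lexicon):
                self._first_chars = self.matcher.first_chars()
            elif isinstance(self.matcher, CharAutomaton):
                self._first_chars = set(self.matcher.transitions[self.matcher.start])
            else:
                return None
        return self._first_chars


@dataclass
class ResourceSet:
    """Ordered resources; order is priority for equal-length overlaps."""

    resources: list[Resource]
    include_list: Lexicon | None = None
    stop_list: Lexicon | None = None
    cost_model: EditCostModel = field(default_factory=EditCostModel)
    normalization: NormalizationTable = field(default_factory=NormalizationTable)

    def __post_init__(self):
        names = [r.name for r in self.resources]
        if len(names) != len(set(names)):
            raise ValueError("duplicate resource names")

    def matching(self):
        return [r for r in self.resources if r.role == "matching"]

    def blocking(self):
        return [r for r in self.resources if r.role == "blocking"]

    def by_name(self, name: str) -> Resource:
        for r in self.resources:
            if r.name == name:
                return r
        raise KeyError(name)

    def without(self, name: str) -> "ResourceSet":
        return ResourceSet(
            resources=[r for r in self.resources if r.name != name],
            include_list=self.include_list,
            stop_list=self.stop_list,
            cost_model=self.cost_model,
            normalization=self.normalization,
        )


@dataclass(frozen=True)
class _Candidate:
    start: int
    end: int
    priority: int
    resource: Resource
    corrections: tuple = ()

    @property
    def length(self) -> int:
        return self.end - self.start


_TOKEN_RE = re.compile(r"[^\s]+")


def _collect_matches(text: str, resources: list[Resource]) -> list[_Candidate]:
    out: list[_Candidate] = []
    for prio, res in enumerate(resources):
        firsts = res.first_chars()
        for pos in range(len(text)):
            if firsts is not None and text[pos] not in firsts:
                continue
            span = res.match_longest(text, pos)
            if span is None or span[1] <= span[0]:
                continue
            # the sum-formula grammar only emits spans with more than
            # two digits (one- and two-digit "formulae" are usually
            # gene/cell-line names or lone element symbols)
            if res.is_sum_formula and \
                    sum(ch.isdigit() for ch in text[span[0]:span[1]]) <= 2:
                continue
            out.append(_Candidate(span[0], span[1], prio, res))
    return out


def _correction_candidates(text: str, covered: list[tuple[int, int]],
                           resources: list[Resource],
                           cost_model: EditCostModel) -> list[_Candidate]:
    """Try spelling correction of uncovered whitespace tokens against
    every correction-enabled resource; keep the cheapest result."""
    correctable = [(p, r) for p, r in enumerate(resources) if r.correction
                   and r.correction.enabled]
    if not correctable:
        return []
    out = []
    for m in _TOKEN_RE.finditer(text):
        tok_start, tok_end = m.start(), m.end()
        token = m.group().strip(".,;:()[]{}")
        if not token:
            continue
        tok_start += m.group().find(token)
        tok_end = tok_start + len(token)
        if any(s < tok_end and tok_start < e for s, e in covered):
            continue
        best: tuple[float, int, CorrectionResult] | None = None
        for prio, res in correctable:
            result = correct_against(res.automaton(), token, cost_model,
                                     res.correction)
            if result is NOT_APPLICABLE or result is None:
                continue
            if result.total_cost == 0:
                continue  # exact matches were already collected
            if best is None or (result.total_cost, prio) < best[:2]:
                best = (result.total_cost, prio, result)
        if best is not None:
            cost, prio, result = best
            out.append(_Candidate(tok_start, tok_end, prio,
                                  resources[prio], corrections=result.edits))
    return out


def _resolve_overlaps(cands: list[_Candidate]) -> list[_Candidate]:
    """Longest span wins; equal spans resolved by manifest priority."""
    chosen: list[_Candidate] = []
    for cand in sorted(cands, key=lambda c: (-c.length, c.priority, c.start)):
        if all(c.end <= cand.start or cand.end <= c.start for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.start)
    return chosen


def annotate_section(doc_id: str, section_label: str, nt: NormalizedText,
                     resources: ResourceSet,
                     correction: bool = True) -> list[Entity]:
    text = nt.text
    blocked_spans = [c for c in _collect_matches(text, resources.blocking())]
    candidates = _collect_matches(text, resources.matching())
    # suppress candidates inside blocking matches
    candidates = [
        c for c in candidates
        if not any(b.start <= c.start and c.end <= b.end for b in blocked_spans)
    ]
    if correction:
        covered = [(c.start, c.end) for c in candidates] + \
                  [(b.start, b.end) for b in blocked_spans]
        candidates += _correction_candidates(
            text, covered, resources.matching(), resources.cost_model)
    entities = []
    for c in _resolve_overlaps(candidates):
        entities.append(Entity.from_norm(
            doc_id, section_label, (c.start, c.end), nt,
            entity_class=c.resource.entity_class,
            resource_name=c.resource.name,
            corrections=c.corrections,
        ))
    return entities


def annotate(doc: SourceDocument, resources: ResourceSet,
             correction: bool = True,
             normalized: dict[str, NormalizedText] | None = None) -> list[Entity]:
    """Annotate every section of a document.

    ``normalized`` optionally receives the per-section normalized texts
    (the post-processing stages need them).
    """
    entities: list[Entity] = []
    for section_label, raw in doc.sections:
        nt = normalize_text(raw, resources.normalization, xml_mode=doc.is_xml)
        if normalized is not None:
            normalized[section_label] = nt
        entities.extend(
            annotate_section(doc.doc_id, section_label, nt, resources, correction))
    return entities


def filter_sum_formula(e: Entity) -> bool:
    """Keep decision for a sum-formula entity: formulae with two or
    fewer digits (CDK2, H2O, CaCo...) are more often not formulae at
    all, so only spans with more than two digit characters survive."""
    return sum(ch.isdigit() for ch in e.text) > 2


def apply_include_stop_lists(entities: list[Entity], nt_by_section: dict,
                             doc: SourceDocument,
                             include_list: Lexicon | None = None,
                             stop_list: Lexicon | None = None,
                             use_stop_list: bool = False) -> list[Entity]:
    """Force-annotate include-list matches and (optionally) drop
    stop-list entities.

    The include list is an ordinary dictionary: its matches are scanned
    like any lexicon and added where they do not conflict with an
    existing longer entity.  The stop list defaults to off — dropping
    partial-entity strings costs more recall than the precision it buys.
    """
    out = list(entities)
    if include_list is not None:
        for section_label, nt in nt_by_section.items():
            existing = [e for e in out if e.section_label == section_label]
            text = nt.text
            for pos in range(len(text)):
                span = include_list.match_longest(text, pos)
                if span is None or span[1] <= span[0]:
                    continue
                conflict = any(
                    e.norm_span and e.norm_span[0] < span[1]
                    and span[0] < e.norm_span[1] for e in existing)
                if conflict:
                    continue
                ent = Entity.from_norm(
                    doc.doc_id, section_label, span, nt,
                    entity_class=include_list.entity_class,
                    resource_name=include_list.name)
                out.append(ent)
                existing.append(ent)
    if use_stop_list and stop_list is not None:
        out = [e for e in out
               if not any(end == len(e.text)
                          for end, _ in stop_list.match_ends(e.text, 0))]
    out.sort(key=lambda e: e.sort_key())
    return out
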