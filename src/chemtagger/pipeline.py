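"""End-to-end annotation pipeline.

Stage order: normalization → resource scanning (with spelling
correction) → five-step entity modification → abbreviation detection →
non-entity abbreviation removal → include/stop lists → sum-formula
digit filter.  Every stage after scanning is post-processing and can be
toggled off independently.  Per-stage entity counts are logged, and at
verbose level each entity's provenance line (resource, corrections,
modification flags) — the auditability the grammar/dictionary approach
exists to provide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .abbrev import (AbbrevConfig, EquivalenceMap, detect_abbreviations,
                     remove_nonentity_abbreviations)
from .engine import (ResourceSet, annotate, apply_include_stop_lists,
                     filter_sum_formula)
from .entities import Entity
from .normalize import SourceDocument
from .postprocess import WordLists, postprocess_entities

__all__ = ["PipelineConfig", "run_pipeline", "StageReport"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles and shared configuration.  Any subset of the
    post-annotation stages may be disabled."""

    xml_mode: bool = False
    correction: bool = True
    entity_modification: bool = True
    abbreviation_detection: bool = True
    nonentity_removal: bool = True
    include_list: bool = True
    stop_list: bool = False          # include list alone performs best
    sum_formula_filter: bool = True
    wordlists: WordLists = field(default_factory=WordLists)
    equivalence_map: EquivalenceMap = field(default_factory=EquivalenceMap)
    abbrev_config: AbbrevConfig = field(default_factory=AbbrevConfig)


@dataclass
class StageReport:
    """Entity counts after each enabled stage, per document."""

    counts: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, entities: list) -> None:
        self.counts[stage] = self.counts.get(stage, 0) + len(entities)


def run_document(doc: SourceDocument, resources: ResourceSet,
                 cfg: PipelineConfig, report: StageReport) -> list[Entity]:
    nts: dict[str, object] = {}
    doc = SourceDocument(doc.doc_id, doc.sections, is_xml=cfg.xml_mode or doc.is_xml)
    entities = annotate(doc, resources, correction=cfg.correction,
                        normalized=nts)
    report.record("annotation", entities)

    by_section: dict[str, list[Entity]] = {}
    for e in entities:
        by_section.setdefault(e.section_label, []).append(e)

    out: list[Entity] = []
    for label, nt in nts.items():
        section_entities = by_section.get(label, [])
        if cfg.entity_modification:
            section_entities = postprocess_entities(section_entities, nt,
                                                    cfg.wordlists)
        if cfg.abbreviation_detection:
            _pairs, new = detect_abbreviations(nt, section_entities,
                                               cfg.equivalence_map,
                                               cfg.abbrev_config)
            section_entities = sorted(section_entities + new,
                                      key=lambda e: e.norm_span)
        if cfg.nonentity_removal:
            section_entities = remove_nonentity_abbreviations(
                nt, section_entities, cfg.abbrev_config)
        out.extend(section_entities)
    if cfg.entity_modification:
        report.record("entity_modification", out)
    if cfg.abbreviation_detection:
        report.record("abbreviation", out)

    if cfg.include_list or cfg.stop_list:
        out = apply_include_stop_lists(
            out, nts, doc,
            include_list=resources.include_list if cfg.include_list else None,
            stop_list=resources.stop_list if cfg.stop_list else None,
            use_stop_list=cfg.stop_list)
        report.record("include_stop_lists", out)

    if cfg.sum_formula_filter:
        out = [e for e in out
               if e.entity_class != "formula" or filter_sum_formula(e)]
        report.record("sum_formula_filter", out)

    for e in out:
        logger.debug("%s %s:%s-%s %r resource=%s corrections=%d flags=%s",
                     e.doc_id, e.section_label, e.span[0], e.span[1], e.text,
                     e.resource_name, len(e.corrections),
                     ",".join(sorted(e.provenance_flags)) or "-")
    out.sort(key=lambda e: e.sort_key())
    return out


def run_pipeline(docs, resources: ResourceSet,
                 cfg: PipelineConfig | None = None,
                 ) -> tuple[list[Entity], StageReport]:
    """Annotate a document collection; returns entities in source
    coordinates plus the per-stage count report."""
    cfg = cfg or PipelineConfig()
    report = StageReport()
    entities: list[Entity] = []
    for doc in docs:
        entities.extend(run_document(doc, resources, cfg, report))
    return entities, report
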