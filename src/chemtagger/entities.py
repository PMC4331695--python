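"""The entity record shared by the annotation and post-processing stages.

An entity is a typed span with full provenance: the grammar or
dictionary that produced it, the spelling corrections applied on the
way, and flags recording every boundary modification.  This is the
auditability contract of the whole system — a surprising annotation can
always be traced to one named resource.

Spans are carried in two coordinate systems: ``norm_span`` on the
normalized character stream the pipeline works over, and ``span``/
``text`` in the original source document (derived through the
normalization index map).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .normalize import NormalizedText, map_span

__all__ = ["Entity", "PROVENANCE_FLAGS"]

PROVENANCE_FLAGS = ("extended", "trimmed", "merged", "abbreviation", "propagated")


@dataclass
class Entity:
    doc_id: str
    section_label: str
    span: tuple[int, int]          # source coordinates, half-open
    text: str                      # source slice
    entity_class: str
    resource_name: str
    corrections: tuple = ()
    provenance_flags: frozenset[str] = frozenset()
    norm_span: tuple[int, int] | None = None

    def __post_init__(self):
        if self.span[0] >= self.span[1]:
            raise ValueError(f"empty entity span {self.span}")
        unknown = set(self.provenance_flags) - set(PROVENANCE_FLAGS)
        if unknown:
            raise ValueError(f"unknown provenance flags {unknown}")

    @classmethod
    def from_norm(cls, doc_id: str, section_label: str,
                  norm_span: tuple[int, int], nt: NormalizedText,
                  entity_class: str, resource_name: str,
                  corrections: tuple = (),
                  provenance_flags: frozenset[str] = frozenset()) -> "Entity":
        span = map_span(norm_span, nt)
        return cls(
            doc_id=doc_id,
            section_label=section_label,
            span=span,
            text=nt.source[span[0]:span[1]],
            entity_class=entity_class,
            resource_name=resource_name,
            corrections=corrections,
            provenance_flags=provenance_flags,
            norm_span=norm_span,
        )

    def moved(self, norm_span: tuple[int, int], nt: NormalizedText,
              add_flags: frozenset[str] = frozenset()) -> "Entity":
        """A copy at new normalized boundaries with extra flags set."""
        span = map_span(norm_span, nt)
        return replace(
            self,
            span=span,
            text=nt.source[span[0]:span[1]],
            norm_span=norm_span,
            provenance_flags=self.provenance_flags | add_flags,
        )

    def flagged(self, *flags: str) -> "Entity":
        return replace(self, provenance_flags=self.provenance_flags | set(flags))

    def overlaps(self, other: "Entity") -> bool:
        a, b = self.norm_span or self.span, other.norm_span or other.span
        return a[0] < b[1] and b[0] < a[1]

    def sort_key(self):
        return (self.doc_id, self.section_label,
                self.norm_span or self.span)
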