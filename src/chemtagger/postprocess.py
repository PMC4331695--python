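"""Rule-based refinement of entity boundaries.

Novel chemical terms are usually built out of known pieces, so the raw
matches from grammars and dictionaries are often fragments of the
mention a curator would annotate.  Five steps, run in a fixed order,
repair this:

1. *Extension* — grow each entity left and right until whitespace, a
   mismatched bracket, or a non-chemical English/noise word.  An entity
   entirely enclosed in balanced brackets is also re-extended from
   outside the brackets, keeping the longer result.  Two entities for
   specific compounds joined by a hyphen are left alone — that shape
   usually denotes a mixture, not one compound.
2. *Trimming* — boundary modifiers that are not part of the name
   ("group", "colloidal", "dye", ...) are stripped.
3. *Merging* — overlapping entities merge; space-separated adjacent
   entities merge into one family name unless one is a known instance
   of the other (a specific compound next to its class name is two
   mentions).
4. *Stop-word removal* — trimming is repeated and entities that reduce
   to an explicitly-unannotated term are dropped.
5. The glutathione-S-transferase special case: the lone ``S`` is
   annotated through its proximity to the glutathione entity.

Every step preserves the original resource attribution and records
itself in the entity's provenance flags, and the full pipeline is
idempotent on its own output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .entities import Entity
from .normalize import NormalizedText
from .wordlists import (COMMON_ENGLISH_WORDS, INSTANCE_OF, NOISE_WORDS,
                        STOP_TERMS, TRIM_TERMS)

__all__ = ["WordLists", "extend_entity", "extend_entities", "trim_entity",
           "merge_entities", "remove_stop_entities", "s_transferase_rule",
           "postprocess_entities", "SPECIFIC_CLASSES"]

#: entity classes that denote a concrete structure (used by the
#: hyphen-mixture exception); generic family classes are excluded
SPECIFIC_CLASSES = frozenset({
    "chemical", "drug", "formula", "cas_number", "registry_number",
    "cid", "element", "allotrope", "alloy", "abbreviation", "alkane",
})

_OPEN = "([{"
_CLOSE = ")]}"
_PAIR = {"(": ")", "[": "]", "{": "}"}
_RPAIR = {v: k for k, v in _PAIR.items()}


@dataclass
class WordLists:
    english_words: frozenset[str] = COMMON_ENGLISH_WORDS
    noise_words: frozenset[str] = NOISE_WORDS
    trim_terms: frozenset[str] = TRIM_TERMS
    stop_terms: frozenset[str] = STOP_TERMS
    instance_of: frozenset[tuple[str, str]] = INSTANCE_OF
    specific_classes: frozenset[str] = SPECIFIC_CLASSES

    def boundary_word(self, chunk: str) -> bool:
        """Case-insensitive whole-word test against the extension
        boundary vocabulary (English, noise and trim words — trim words
        must not be re-absorbed by extension or the pipeline would not
        be idempotent)."""
        core = chunk.strip("()[]{}0123456789").lower()
        return bool(core) and (core in self.english_words
                               or core in self.noise_words
                               or core in self.trim_terms)

    def is_instance(self, a: str, b: str) -> bool:
        pair = (a.strip().lower(), b.strip().lower())
        return pair in self.instance_of or (pair[1], pair[0]) in self.instance_of


def _chunk_right(text: str, pos: int) -> str:
    j = pos
    while j < len(text) and not text[j].isspace() and text[j] != "-":
        j += 1
    return text[pos:j]


def _chunk_left(text: str, pos: int) -> str:
    j = pos
    while j > 0 and not text[j - 1].isspace() and text[j - 1] != "-":
        j -= 1
    return text[j:pos]


def _extend_right(text: str, start: int, end: int, wl: WordLists,
                  specific: bool, specific_starts: set[int]) -> int:
    pos = end
    stack: list[int] = []  # positions of yet-unmatched openers
    stack_chars: list[str] = []
    while pos < len(text):
        ch = text[pos]
        if ch.isspace():
            break
        # sentence punctuation (not the structural commas inside names
        # like 2,4-D): boundary when followed by space, end, or a closer
        if ch in ".,;:" and (pos + 1 == len(text) or text[pos + 1].isspace()
                             or text[pos + 1] in ".,;:)]}"):
            break
        if ch == "-":
            chunk = _chunk_right(text, pos + 1)
            if not chunk:
                break  # bare trailing hyphen
            if wl.boundary_word(chunk):
                break
            if specific and (pos + 1) in specific_starts:
                break  # hyphen-joined specific compounds: a mixture
            pos += 1
            continue
        if ch in _CLOSE:
            if stack_chars and stack_chars[-1] == _RPAIR[ch]:
                stack.pop()
                stack_chars.pop()
                pos += 1
                continue
            break  # mismatched closing bracket
        if ch in _OPEN:
            stack.append(pos)
            stack_chars.append(ch)
            pos += 1
            continue
        j = pos
        while j < len(text) and not text[j].isspace() and text[j] != "-" \
                and text[j] not in _OPEN and text[j] not in _CLOSE:
            j += 1
        if wl.boundary_word(text[pos:j]):
            break
        pos = j
    if stack:  # never keep an unmatched opener
        pos = stack[0]
    return pos


def _extend_left(text: str, start: int, end: int, wl: WordLists,
                 specific: bool, specific_ends: set[int]) -> int:
    pos = start
    stack: list[int] = []  # positions of yet-unmatched closers (leftward scan)
    stack_chars: list[str] = []
    while pos > 0:
        ch = text[pos - 1]
        if ch.isspace():
            break
        if ch in ".,;:" and (pos - 1 == 0 or text[pos - 2].isspace()
                             or text[pos - 2] in ".,;:([{"):
            break
        if ch == "-":
            chunk = _chunk_left(text, pos - 1)
            if not chunk:
                break
            if wl.boundary_word(chunk):
                break
            if specific and (pos - 1) in specific_ends:
                break
            pos -= 1
            continue
        if ch in _OPEN:
            if stack_chars and stack_chars[-1] == _PAIR[ch]:
                stack.pop()
                stack_chars.pop()
                pos -= 1
                continue
            break
        if ch in _CLOSE:
            stack.append(pos - 1)
            stack_chars.append(ch)
            pos -= 1
            continue
        j = pos
        while j > 0 and not text[j - 1].isspace() and text[j - 1] != "-" \
                and text[j - 1] not in _OPEN and text[j - 1] not in _CLOSE:
            j -= 1
        if wl.boundary_word(text[j:pos]):
            break
        pos = j
    if stack:
        pos = stack[0] + 1
    return pos


def _extend_span(text: str, span: tuple[int, int], wl: WordLists,
                 specific: bool, specific_starts: set[int],
                 specific_ends: set[int], depth: int = 0) -> tuple[int, int]:
    start, end = span
    new_start = _extend_left(text, start, end, wl, specific, specific_ends)
    new_end = _extend_right(text, start, end, wl, specific, specific_starts)
    best = (new_start, new_end)
    # entirely enclosed in balanced brackets: retry from outside them,
    # but only adopt the outer boundaries if extension actually grew
    # past the bracket pair (merely wrapping the brackets gains nothing)
    if depth < 8 and start > 0 and end < len(text) and text[start - 1] in _OPEN \
            and text[end] == _PAIR[text[start - 1]]:
        outer = _extend_span(text, (start - 1, end + 1), wl, specific,
                             specific_starts, specific_ends, depth + 1)
        if outer != (start - 1, end + 1) \
                and outer[1] - outer[0] > best[1] - best[0]:
            best = outer
    return best


def extend_entity(e: Entity, nt: NormalizedText, wl: WordLists,
                  others: tuple[Entity, ...] = ()) -> Entity:
    """Step 1 for a single entity; ``others`` supplies the neighbours
    consulted by the hyphen-mixture exception."""
    specific = e.entity_class in wl.specific_classes
    specific_starts = {o.norm_span[0] for o in others
                       if o is not e and o.norm_span
                       and o.entity_class in wl.specific_classes}
    specific_ends = {o.norm_span[1] for o in others
                     if o is not e and o.norm_span
                     and o.entity_class in wl.specific_classes}
    span = _extend_span(nt.text, e.norm_span, wl, specific,
                        specific_starts, specific_ends)
    if span == e.norm_span:
        return e
    return e.moved(span, nt, frozenset({"extended"}))


def extend_entities(entities: list[Entity], nt: NormalizedText,
                    wl: WordLists) -> list[Entity]:
    others = tuple(entities)
    return [extend_entity(e, nt, wl, others) for e in entities]


_LEAD_TRIM_RE = re.compile(r"^([^\s-]+)([\s-]+)")
_TAIL_TRIM_RE = re.compile(r"([\s-]+)([^\s-]+)$")


def trim_entity(e: Entity, nt: NormalizedText, wl: WordLists) -> Entity | None:
    """Step 2: strip boundary trim terms (with their connecting
    whitespace/hyphens); an entity trimmed to nothing is removed."""
    start, end = e.norm_span
    text = nt.text
    changed = True
    while changed and start < end:
        changed = False
        seg = text[start:end]
        m = _LEAD_TRIM_RE.match(seg)
        if m and m.group(1).lower() in wl.trim_terms:
            start += m.end()
            changed = True
            continue
        m = _TAIL_TRIM_RE.search(seg)
        if m and m.group(2).lower() in wl.trim_terms:
            end -= len(m.group(0))
            changed = True
            continue
        # entity that is nothing but a trim term
        if seg.lower() in wl.trim_terms:
            return None
    if start >= end:
        return None
    if (start, end) == e.norm_span:
        return e
    return e.moved((start, end), nt, frozenset({"trimmed"}))


def merge_entities(entities: list[Entity], nt: NormalizedText,
                   wl: WordLists) -> list[Entity]:
    """Step 3: merge overlapping entities, and space-separated adjacent
    entities unless one is an instance of the other."""
    if not entities:
        return []
    ordered = sorted(entities, key=lambda e: e.norm_span)
    out = [ordered[0]]
    for e in ordered[1:]:
        prev = out[-1]
        p_start, p_end = prev.norm_span
        start, end = e.norm_span
        overlapping = start < p_end
        gap = nt.text[p_end:start]
        adjacent = (not overlapping) and gap == " " \
            and not wl.is_instance(prev.text, e.text)
        if overlapping or adjacent:
            merged_span = (p_start, max(p_end, end))
            resource = prev.resource_name if prev.resource_name == e.resource_name \
                else f"{prev.resource_name}+{e.resource_name}"
            cls = prev.entity_class if prev.entity_class == e.entity_class \
                else f"{prev.entity_class}+{e.entity_class}"
            merged = prev.moved(merged_span, nt, frozenset({"merged"}))
            merged.resource_name = resource
            merged.entity_class = cls
            merged.corrections = tuple(prev.corrections) + tuple(e.corrections)
            out[-1] = merged
        else:
            out.append(e)
    return out


def remove_stop_entities(entities: list[Entity], nt: NormalizedText,
                         wl: WordLists) -> list[Entity]:
    """Step 4: re-trim, then drop entities whose remaining text is a
    stop term (whole-entity test only)."""
    out: list[Entity] = []
    for e in entities:
        trimmed = trim_entity(e, nt, wl)
        if trimmed is None:
            continue
        if trimmed.text.strip().lower() in wl.stop_terms:
            continue
        out.append(trimmed)
    return out


#: surface patterns for the S-transferase proximity rule; group 1 is
#: the part annotated together with the glutathione entity
S_TRANSFERASE_PATTERNS = (
    re.compile(r"(glutathione-S)-transferase", re.IGNORECASE),
    re.compile(r"(glutathione S)-transferase", re.IGNORECASE),
)


def s_transferase_rule(entities: list[Entity], nt: NormalizedText) -> list[Entity]:
    """Step 5: inside ``glutathione(-| )S-transferase`` the ``S`` is
    covered by extending the glutathione entity over it."""
    out = list(entities)
    for pattern in S_TRANSFERASE_PATTERNS:
        for m in pattern.finditer(nt.text):
            for i, e in enumerate(out):
                if e.norm_span and e.norm_span[0] == m.start(1) \
                        and m.start(1) < e.norm_span[1] <= m.end(1):
                    out[i] = e.moved((m.start(1), m.end(1)), nt,
                                     frozenset({"extended"}))
    return out


def postprocess_entities(entities: list[Entity], nt: NormalizedText,
                         wl: WordLists | None = None) -> list[Entity]:
    """The full five-step pipeline over one document section."""
    wl = wl or WordLists()
    out = extend_entities(entities, nt, wl)
    out = [t for t in (trim_entity(e, nt, wl) for e in out) if t is not None]
    out = merge_entities(out, nt, wl)
    out = remove_stop_entities(out, nt, wl)
    out = s_transferase_rule(out, nt)
    return out
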