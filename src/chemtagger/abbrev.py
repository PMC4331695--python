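"""Abbreviation detection and non-entity abbreviation removal.

Definitions pair a *long form* (LF) with a *short form* (SF) in one of
six surface shapes::

    Tetrahydrofuran (THF)      LF (SF)
    THF (tetrahydrofuran)      SF (LF)
    Tetrahydrofuran (THF;      LF (SF;
    Tetrahydrofuran (THF,      LF (SF,
    (tetrahydrofuran, THF)     (LF, SF)
    THF = tetrahydrofuran      SF = LF

Classic definition mining has to guess where the long form starts; here
the long forms are the entities the annotator already found, which
removes that guess for detection.  A candidate short form must be at
least a configurable minimum length (3 by default, matching mention
annotation guidelines), have balanced brackets, and must not be a Roman
numeral or a compound identifier like ``1a``.  The pairing test is the
character-correspondence condition: every alphanumeric character of the
short form must appear, in order, in the long form, with the first
short-form character matching a word-initial character.  A token
equivalence map (mercury→Hg, methyl→Me, ...) is applied to the long
form first so that ``MeHg`` is accepted for ``methylmercury``.

Once a pair is accepted, every further instance of the short-form
string in the same document is annotated with the long form's class and
resource.  The same machinery runs in reverse for false-positive
removal: an entity that itself sits in a definition pattern whose
discovered long form is *not* an entity is assumed to be an
abbreviation of something non-chemical and is removed everywhere in the
document (the "current good manufacturing practice (cGMP)" case).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .entities import Entity
from .normalize import NormalizedText
from .wordlists import EQUIVALENCE_MAP

__all__ = [
    "AbbrevConfig",
    "AbbrevPair",
    "EquivalenceMap",
    "is_valid_short_form",
    "corresponds",
    "detect_abbreviations",
    "remove_nonentity_abbreviations",
]

_ROMAN_RE = re.compile(r"^[IVXLCDMivxlcdm]+$")
_IDENTIFIER_RE = re.compile(r"^(?:\d+[A-Za-z]+|[A-Za-z]\d+)$")


@dataclass(frozen=True)
class AbbrevConfig:
    min_length: int = 3
    roman_numeral_check: bool = True
    identifier_check: bool = True

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class EquivalenceMap:
    """Long-token → short-token rewrites (e.g. mercury → Hg)."""

    pairs: dict[str, str] = field(default_factory=lambda: dict(EQUIVALENCE_MAP))

    def rewrite(self, long_form: str) -> str:
        """Greedily rewrite long-form substrings, longest token first."""
        out = long_form
        for token in sorted(self.pairs, key=len, reverse=True):
            out = re.sub(re.escape(token), self.pairs[token], out,
                         flags=re.IGNORECASE)
        return out


@dataclass(frozen=True)
class AbbrevPair:
    short_form: str
    short_span: tuple[int, int]      # normalized coordinates
    long_form: Entity
    pattern_form: str                # one of the six form labels


def _brackets_balanced(s: str) -> bool:
    pairs = {")": "(", "]": "[", "}": "{"}
    stack: list[str] = []
    for ch in s:
        if ch in "([{":
            stack.append(ch)
        elif ch in pairs:
            if not stack or stack[-1] != pairs[ch]:
                return False
            stack.pop()
    return not stack


def is_valid_short_form(candidate: str, cfg: AbbrevConfig | None = None) -> bool:
    cfg = cfg or AbbrevConfig()
    candidate = candidate.strip()
    if len(candidate) < cfg.min_length:
        return False
    if not _brackets_balanced(candidate):
        return False
    if not any(ch.isalnum() for ch in candidate):
        return False
    if cfg.roman_numeral_check and _ROMAN_RE.match(candidate):
        return False
    if cfg.identifier_check and len(candidate) <= 3 \
            and _IDENTIFIER_RE.match(candidate):
        return False
    return True


def corresponds(short: str, long: str, eq: EquivalenceMap | None = None) -> bool:
    """Character-correspondence test: the short form's alphanumerics
    appear in order in the (equivalence-rewritten) long form, and its
    first character matches a word-initial long-form character."""
    if eq is not None:
        long = eq.rewrite(long)
    sf = [ch for ch in short if ch.isalnum()]
    if not sf:
        return False
    # positions where a word starts in the long form
    word_initial = {i for i, ch in enumerate(long)
                    if ch.isalnum() and (i == 0 or not long[i - 1].isalnum())}
    # greedy in-order match, anchored at a word-initial first character
    for anchor in sorted(word_initial):
        if long[anchor].lower() != sf[0].lower():
            continue
        i = anchor + 1
        ok = True
        for ch in sf[1:]:
            while i < len(long) and long[i].lower() != ch.lower():
                i += 1
            if i == len(long):
                ok = False
                break
            i += 1
        if ok:
            return True
    return False


# sentence-ish segment bounds: paragraph breaks only (no sentence splitting)
def _segment_bounds(text: str, pos: int) -> tuple[int, int]:
    start = text.rfind("\n", 0, pos) + 1
    end = text.find("\n", pos)
    return start, len(text) if end == -1 else end


_WORD_RE = re.compile(r"\S+")


def detect_abbreviations(nt: NormalizedText, entities: list[Entity],
                         eq: EquivalenceMap | None = None,
                         cfg: AbbrevConfig | None = None,
                         ) -> tuple[list[AbbrevPair], list[Entity]]:
    """Find definition pairs whose long form is an already-found entity
    and annotate every instance of each accepted short form.

    Returns the accepted pairs and the newly created entities (flagged
    ``abbreviation`` at the defining occurrence, ``propagated``
    elsewhere).
    """
    eq = eq or EquivalenceMap()
    cfg = cfg or AbbrevConfig()
    text = nt.text
    by_end = {e.norm_span[1]: e for e in entities if e.norm_span}
    by_start = {e.norm_span[0]: e for e in entities if e.norm_span}
    pairs: list[AbbrevPair] = []

    def try_pair(sf: str, sf_span: tuple[int, int], lf: Entity | None,
                 form: str) -> None:
        if lf is None:
            return
        sf = sf.strip()
        if not is_valid_short_form(sf, cfg):
            return
        if not corresponds(sf, lf.text, eq):
            return
        pairs.append(AbbrevPair(sf, sf_span, lf, form))

    # bracketed forms; a depth-tracking scan so that short forms may
    # themselves contain balanced brackets
    for p, ch in enumerate(text):
        if ch != "(":
            continue
        depth = 1
        i = p + 1
        closer = None
        while i < len(text) and i - p <= 80:
            c = text[i]
            if c == "\n":
                break
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth == 0:
                    closer = ")"
                    break
            elif c in ";," and depth == 1:
                closer = c
                break
            i += 1
        if closer is None:
            continue
        inner = text[p + 1:i]

        # (LF, SF): the entity sits inside the brackets before a comma
        if closer == ",":
            inner_lf = by_start.get(p + 1)
            if inner_lf is not None and inner_lf.norm_span[1] == i:
                close = text.find(")", i + 1)
                nl = text.find("\n", i + 1)
                if close != -1 and (nl == -1 or close < nl):
                    sf_text = text[i + 1:close].strip()
                    sf_begin = i + 1 + text[i + 1:close].find(sf_text)
                    try_pair(sf_text, (sf_begin, sf_begin + len(sf_text)),
                             inner_lf, "(LF, SF)")
                    continue

        # SF (LF): the entity is exactly the bracket content
        if closer == ")":
            lf_inside = by_start.get(p + 1)
            if lf_inside is not None and lf_inside.norm_span[1] == i \
                    and p >= 2 and text[p - 1] == " ":
                w = _WORD_RE.findall(text[:p - 1])
                if w:
                    sf = w[-1]
                    sf_start = text.rfind(sf, 0, p - 1)
                    try_pair(sf, (sf_start, sf_start + len(sf)),
                             lf_inside, "SF (LF)")

        # LF (SF) / LF (SF; / LF (SF, : long-form entity just before
        if p >= 1 and text[p - 1] == " ":
            lf = by_end.get(p - 1)
            form = {")": "LF (SF)", ";": "LF (SF;", ",": "LF (SF,"}[closer]
            try_pair(inner, (p + 1, i), lf, form)

    # SF = LF
    for m in re.finditer(r"(\S+) ?= ?(\S)", text):
        lf = by_start.get(m.start(2))
        if lf is not None and "=" not in m.group(1):
            try_pair(m.group(1), (m.start(1), m.end(1)), lf, "SF = LF")

    # propagate: annotate every instance of each accepted short form
    new_entities: list[Entity] = []
    taken = [e.norm_span for e in entities if e.norm_span]
    seen_sf: set[str] = set()
    for pair in pairs:
        if pair.short_form in seen_sf:
            continue
        seen_sf.add(pair.short_form)
        for m in re.finditer(re.escape(pair.short_form), text):
            span = (m.start(), m.end())
            # exact-token occurrence: not embedded in a larger word
            if m.start() > 0 and text[m.start() - 1].isalnum():
                continue
            if m.end() < len(text) and text[m.end()].isalnum():
                continue
            if any(s[0] < span[1] and span[0] < s[1] for s in taken):
                continue
            flag = "abbreviation" if span == pair.short_span else "propagated"
            new_entities.append(Entity.from_norm(
                pair.long_form.doc_id, pair.long_form.section_label, span, nt,
                entity_class=pair.long_form.entity_class,
                resource_name=pair.long_form.resource_name,
                provenance_flags=frozenset({flag})))
            taken.append(span)
    return pairs, new_entities


def _find_long_form(sf: str, candidate: str) -> int | None:
    """Right-to-left long-form search in ``candidate`` (the text
    immediately before the definition bracket): returns the offset in
    ``candidate`` where the long form starts, or None.

    The long form may span at most min(|SF| + 5, |SF| * 2) words.
    """
    sf_chars = [ch.lower() for ch in sf if ch.isalnum()]
    if not sf_chars:
        return None
    i = len(candidate) - 1
    for ch in reversed(sf_chars):
        while i >= 0 and candidate[i].lower() != ch:
            i -= 1
        if i < 0:
            return None
        i -= 1
    start = i + 1
    # the first short-form character must match a word-initial character
    if start > 0 and not candidate[start - 1].isspace():
        return None
    n_words = len(_WORD_RE.findall(candidate[start:]))
    if n_words > min(len(sf_chars) + 5, len(sf_chars) * 2):
        return None
    return start


def remove_nonentity_abbreviations(nt: NormalizedText, entities: list[Entity],
                                   cfg: AbbrevConfig | None = None) -> list[Entity]:
    """Drop entities that are abbreviations of non-entities.

    For each entity appearing as the short form of a definition pattern,
    the long form is searched in the enclosing paragraph segment; if one
    is found and it neither is nor overlaps an entity, the entity and
    all other instances of its text are removed.
    """
    cfg = cfg or AbbrevConfig()
    text = nt.text
    spans = [e.norm_span for e in entities if e.norm_span]
    to_remove: set[str] = set()
    for e in entities:
        if e.norm_span is None:
            continue
        start, end = e.norm_span
        # pattern "LF (SF" — entity directly after an opening bracket
        if start < 2 or text[start - 1] != "(" or end >= len(text) \
                or text[end] not in ");,":
            continue
        if not is_valid_short_form(e.text, cfg):
            continue
        # the entity may itself be the long form of a "(LF, SF)"
        # definition; in that shape it is no abbreviation candidate
        if text[end] == ",":
            close = text.find(")", end + 1)
            nl = text.find("\n", end + 1)
            if close != -1 and (nl == -1 or close < nl) \
                    and corresponds(text[end + 1:close].strip(), e.text):
                continue
        seg_start, _ = _segment_bounds(text, start)
        before = text[seg_start:start - 1].rstrip()
        lf_off = _find_long_form(e.text, before)
        if lf_off is None:
            continue
        lf_span = (seg_start + lf_off, seg_start + len(before))
        overlaps_entity = any(
            s[0] < lf_span[1] and lf_span[0] < s[1] for s in spans
            if s != e.norm_span)
        if not overlaps_entity:
            to_remove.add(e.text)
    if not to_remove:
        return list(entities)
    return [e for e in entities if e.text not in to_remove]
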