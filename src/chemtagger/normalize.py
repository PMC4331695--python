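"""Character normalization with source-offset bookkeeping.

Scientific text is full of typographically distinct characters with
identical meaning to a chemical-name matcher: backtick, curly quotes and
prime all act as an apostrophe, en/em dashes act as hyphens, ligatures
like ``œ`` expand to two letters. Normalizing these up front means the
downstream grammars and dictionaries only need to be written over a
small, canonical alphabet. Every normalized character remembers the
half-open range of source characters it came from, so entity spans found
on the normalized stream can be reported in coordinates of the original
document.

Offsets are 0-based, half-open and counted in Unicode code points of the
original text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_TABLE",
    "NormalizationError",
    "NormalizationTable",
    "NormalizedText",
    "SourceDocument",
    "normalize_text",
    "map_span",
]

#: Default character replacements.  The set is deliberately small and
#: config-extensible; it canonicalizes quote-like marks to the apostrophe,
#: dash-like marks to the hyphen-minus, and expands latin ligatures.
DEFAULT_TABLE: dict[str, str] = {
    "`": "'",
    "‘": "'",  # left single quote
    "’": "'",  # right single quote
    "′": "'",  # prime
    "“": '"',
    "”": '"',
    "–": "-",  # en dash
    "—": "-",  # em dash
    "−": "-",  # minus sign
    "œ": "oe",  # œ
    "Œ": "Oe",  # Œ
    "æ": "ae",  # æ
    "Æ": "Ae",  # Æ
    " ": " ",  # no-break space
}

#: XML tags treated as purely stylistic: the tag is dropped and its
#: content is kept inline.  All other tags delimit paragraphs.
STYLISTIC_TAGS = frozenset({"sub", "sup", "i", "b"})


class NormalizationError(ValueError):
    """Malformed markup; carries the source offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class NormalizationTable:
    """Mapping from source characters/sequences to replacement strings."""

    char_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TABLE))

    def __post_init__(self):
        for key in self.char_map:
            if not key:
                raise ValueError("empty key in normalization table")

    @classmethod
    def from_config(cls, mapping: dict[str, str]) -> "NormalizationTable":
        table = dict(DEFAULT_TABLE)
        table.update(mapping)
        return cls(table)


@dataclass(frozen=True)
class SourceDocument:
    """A document as received: an id plus ordered labelled sections.

    Section labels follow the title/abstract/paragraph convention
    (``T``, ``A``, ``P``).
    """

    doc_id: str
    sections: tuple[tuple[str, str], ...]
    is_xml: bool = False

    def __post_init__(self):
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        for label, _ in self.sections:
            if label not in ("T", "A", "P"):
                raise ValueError(f"unknown section label {label!r}")


@dataclass
class NormalizedText:
    """Normalized character stream plus the map back to source offsets.

    ``index_map[i]`` is the half-open source range that produced
    normalized character ``i``.  Inserted paragraph-break newlines map to
    an empty range at the position where the break occurred.
    """

    text: str
    index_map: list[tuple[int, int]]
    paragraph_breaks: set[int] = field(default_factory=set)
    source: str = ""  # the raw input, kept for source-coordinate slicing

    def __post_init__(self):
        if len(self.text) != len(self.index_map):
            raise ValueError("index_map length must equal text length")


_TAG_RE = re.compile(r"<(/?)([A-Za-z][\w:-]*)((?:[^>\"']|\"[^\"]*\"|'[^']*')*?)(/?)>")


def _apply_table(raw: str, table: NormalizationTable, base: int,
                 out: list[str], index_map: list[tuple[int, int]]) -> None:
    """Append the normalized form of ``raw`` to ``out``/``index_map``.

    ``base`` is the source offset of raw[0].  Multi-character table keys
    are matched longest-first at each position.
    """
    keys_by_len = sorted(table.char_map, key=len, reverse=True)
    multi = [k for k in keys_by_len if len(k) > 1]
    i = 0
    n = len(raw)
    while i < n:
        matched = None
        for key in multi:
            if raw.startswith(key, i):
                matched = key
                break
        if matched is None and raw[i] in table.char_map:
            matched = raw[i]
        if matched is None:
            out.append(raw[i])
            index_map.append((base + i, base + i + 1))
            i += 1
        else:
            repl = table.char_map[matched]
            src = (base + i, base + i + len(matched))
            for ch in repl:
                out.append(ch)
                index_map.append(src)
            i += len(matched)


def normalize_text(raw: str, table: NormalizationTable | None = None,
                   xml_mode: bool = False,
                   stylistic_tags: frozenset[str] = STYLISTIC_TAGS) -> NormalizedText:
    """Normalize ``raw`` and build the offset map.

    In ``xml_mode`` stylistic tags (default ``sub``/``sup``/``i``/``b``)
    are removed while keeping their content, and every other tag is
    replaced by a paragraph break (a newline mapping to an empty source
    range). Tag nesting is checked; a malformed tag or mismatched close
    raises :class:`NormalizationError` naming the offset.
    """
    table = table or NormalizationTable()
    out: list[str] = []
    index_map: list[tuple[int, int]] = []
    breaks: set[int] = set()

    if not xml_mode:
        _apply_table(raw, table, 0, out, index_map)
        return NormalizedText("".join(out), index_map, breaks, source=raw)

    stack: list[str] = []
    pos = 0

    def add_break(at: int) -> None:
        # collapse consecutive breaks
        if out and out[-1] == "\n":
            return
        if not out:  # no leading break
            return
        out.append("\n")
        index_map.append((at, at))
        breaks.add(len(out) - 1)

    while pos < len(raw):
        lt = raw.find("<", pos)
        if lt == -1:
            _apply_table(raw[pos:], table, pos, out, index_map)
            break
        if lt > pos:
            _apply_table(raw[pos:lt], table, pos, out, index_map)
        m = _TAG_RE.match(raw, lt)
        if m is None:
            raise NormalizationError("malformed tag", lt)
        closing, name, _attrs, selfclose = m.groups()
        name = name.lower()
        if closing:
            if not stack:
                raise NormalizationError(f"unmatched closing tag </{name}>", lt)
            expected = stack.pop()
            if expected != name:
                raise NormalizationError(
                    f"mismatched closing tag </{name}>, expected </{expected}>", lt)
            if name not in stylistic_tags:
                add_break(m.end())
        elif selfclose:
            if name not in stylistic_tags:
                add_break(m.end())
        else:
            stack.append(name)
            if name not in stylistic_tags:
                add_break(lt)
        pos = m.end()
    if stack:
        raise NormalizationError(f"unclosed tag <{stack[-1]}>", len(raw))
    # strip a trailing break
    while out and out[-1] == "\n" and (len(out) - 1) in breaks:
        breaks.discard(len(out) - 1)
        out.pop()
        index_map.pop()
    return NormalizedText("".join(out), index_map, breaks, source=raw)


def map_span(span: tuple[int, int], nt: NormalizedText) -> tuple[int, int]:
    """Map a normalized half-open span to the minimal covering source range."""
    start, end = span
    if start < 0 or end > len(nt.text) or start > end:
        raise IndexError(f"span {span} out of bounds for text of length {len(nt.text)}")
    if start == end:
        if start < len(nt.index_map):
            p = nt.index_map[start][0]
        elif nt.index_map:
            p = nt.index_map[-1][1]
        else:
            p = 0
        return (p, p)
    ranges = nt.index_map[start:end]
    return (min(r[0] for r in ranges), max(r[1] for r in ranges))
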