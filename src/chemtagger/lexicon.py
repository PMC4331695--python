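"""Named term lists compiled for longest-match scanning.

A lexicon is a dictionary of surface forms sharing an entity class and a
matching policy.  Most chemical-name dictionaries are matched with a
case-insensitive *first* letter but case-sensitive remainder, so that a
sentence-initial capital does not break a match while acronym casing is
preserved; English-word and noise dictionaries are matched fully
case-insensitively and only at token boundaries.  A lexicon can play a
*matching* role (its hits become entities) or a *blocking* role (its
hits only suppress other matches).

Matching is a walk down a character trie; like grammar matching, a span
is only valid when the round/square/curly brackets inside it are
balanced and well nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .grammar import BracketTracker, CharAutomaton

__all__ = ["Lexicon", "build_lexicon", "match_lexicon", "load_term_file"]

CASE_POLICIES = ("sensitive", "insensitive", "first-insensitive", "per-term")

#: characters that may not flank a token-bounded match
_WORD_CHARS = "letters/digits"


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


class _Trie:
    __slots__ = ("children", "terminal")

    def __init__(self):
        self.children: dict[str, _Trie] = {}
        self.terminal: str | None = None  # canonical term ending here


@dataclass
class Lexicon:
    """A compiled named term collection.

    Parameters mirror the per-dictionary configuration: ``entity_class``
    is the label given to entities this lexicon produces, ``role`` is
    ``matching`` or ``blocking``, ``case_policy`` one of
    ``sensitive | insensitive | first-insensitive | per-term`` and
    ``token_boundary`` requires matches to start and end at non-word
    boundaries (used for English-word resources, off for chemical names
    so that partial, extendable matches remain possible).
    ``correction`` optionally names the spelling-correction settings for
    this resource (resolved by the annotation engine).
    """

    name: str
    terms: set[str]
    entity_class: str = "chemical"
    case_policy: str = "first-insensitive"
    role: str = "matching"
    token_boundary: bool = False
    correction: object | None = None
    #: per-term case-sensitivity flags, used when case_policy == "per-term"
    case_sensitive_terms: set[str] = field(default_factory=set)
    _trie: _Trie | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"lexicon {self.name!r}: empty term list")
        if any(not t for t in self.terms):
            raise ValueError(f"lexicon {self.name!r}: empty term")
        if self.case_policy not in CASE_POLICIES:
            raise ValueError(f"unknown case policy {self.case_policy!r}")
        if self.role not in ("matching", "blocking"):
            raise ValueError(f"unknown role {self.role!r}")
        self._compile()

    # -- compilation -------------------------------------------------------
    def _fold(self, term: str) -> str:
        if self.case_policy == "insensitive":
            return term.lower()
        if self.case_policy == "first-insensitive":
            return term[:1].lower() + term[1:]
        if self.case_policy == "per-term" and term not in self.case_sensitive_terms:
            return term.lower()
        return term

    def _fold_char(self, ch: str, depth: int) -> str:
        if self.case_policy == "insensitive":
            return ch.lower()
        if self.case_policy == "first-insensitive":
            return ch.lower() if depth == 0 else ch
        return ch

    def _compile(self) -> None:
        root = _Trie()
        for term in self.terms:
            folded = self._fold(term)
            node = root
            for ch in folded:
                node = node.children.setdefault(ch, _Trie())
            node.terminal = term
            if self.case_policy == "per-term" and term not in self.case_sensitive_terms:
                # also allow arbitrary-case text for insensitive terms:
                # folding of the text side handles it (see _walk)
                pass
        object.__setattr__(self, "_trie", root)

    # -- matching ----------------------------------------------------------
    def match_ends(self, text: str, pos: int, track_brackets: bool = True):
        """Yield (end, term) for every lexicon term matching at ``pos``.

        For per-term lexicons both the verbatim and the case-folded trie
        branches are followed, so a sensitive acronym and an insensitive
        name sharing a prefix are both reachable.
        """
        nodes = [self._trie]
        tracker = BracketTracker()
        two_way = self.case_policy == "per-term"
        i = pos
        n = len(text)
        while i < n and nodes:
            raw = text[i]
            tracker.feed(raw)
            ch = self._fold_char(raw, i - pos)
            nxt_nodes = []
            for node in nodes:
                nxt = node.children.get(ch)
                if nxt is not None:
                    nxt_nodes.append(nxt)
                if two_way and ch.lower() != ch:
                    nxt = node.children.get(ch.lower())
                    if nxt is not None:
                        nxt_nodes.append(nxt)
            nodes = nxt_nodes
            i += 1
            if not track_brackets or tracker.balanced:
                for node in nodes:
                    if node.terminal is not None:
                        yield i, node.terminal
                        break

    def match_longest(self, text: str, pos: int) -> tuple[int, int] | None:
        """Longest valid term span at ``pos`` (token boundary enforced
        when the lexicon requires it)."""
        if self.token_boundary and 0 < pos < len(text) \
                and _is_word_char(text[pos - 1]) and _is_word_char(text[pos]):
            return None
        best = None
        for end, _term in self.match_ends(text, pos):
            if self.token_boundary and end < len(text) \
                    and _is_word_char(text[end]) and _is_word_char(text[end - 1]):
                continue
            best = (pos, end)
        return best

    def first_chars(self) -> set[str]:
        """Possible first characters of any term, under the case policy
        (used by the scanner to skip candidate positions cheaply)."""
        chars: set[str] = set()
        for term in self.terms:
            c = term[0]
            if self.case_policy in ("insensitive", "first-insensitive"):
                chars.add(c.lower())
                chars.add(c.upper())
            elif self.case_policy == "per-term" and term not in self.case_sensitive_terms:
                chars.add(c.lower())
                chars.add(c.upper())
            else:
                chars.add(c)
        return chars

    def to_automaton(self) -> CharAutomaton:
        """The lexicon as a character DFA (the spelling-correction target).

        Case policy is applied by alphabet folding at build time.
        """
        if self.case_policy == "insensitive":
            return CharAutomaton.from_terms(self.terms, case_insensitive=True)
        if self.case_policy == "first-insensitive":
            expanded = set()
            for t in self.terms:
                expanded.add(t[:1].lower() + t[1:])
                expanded.add(t[:1].upper() + t[1:])
            return CharAutomaton.from_terms(expanded)
        if self.case_policy == "per-term":
            auto_terms = set()
            for t in self.terms:
                if t in self.case_sensitive_terms:
                    auto_terms.add(t)
                else:
                    auto_terms.add(t.lower())
            return CharAutomaton.from_terms(auto_terms)  # approximation
        return CharAutomaton.from_terms(self.terms)

    def __contains__(self, text: str) -> bool:
        return any(end == len(text) for end, _ in self.match_ends(text, 0))


def build_lexicon(terms, name: str = "lexicon", **config) -> Lexicon:
    """Compile a term iterable into a :class:`Lexicon` (see class docs
    for the config keys)."""
    return Lexicon(name=name, terms=set(terms), **config)


def match_lexicon(lex: Lexicon, text: str, pos: int) -> tuple[int, int] | None:
    """Longest valid term span of ``lex`` at ``pos``, or ``None``."""
    if pos > len(text):
        raise IndexError(f"pos {pos} beyond end of text")
    if pos == len(text):
        return None
    return lex.match_longest(text, pos)


def load_term_file(path: str | Path) -> tuple[set[str], set[str]]:
    """Read a one-term-per-line UTF-8 file.

    An optional tab-separated second column carrying ``cs`` flags a term
    as case-sensitive (for per-term lexicons).  Returns
    ``(terms, case_sensitive_terms)``; blank lines and ``#`` comments
    are skipped.
    """
    terms: set[str] = set()
    cs: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        term = parts[0]
        terms.add(term)
        if len(parts) > 1 and parts[1].strip() == "cs":
            cs.add(term)
    return terms, cs
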