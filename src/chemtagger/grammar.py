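"""Regular grammars for nomenclature, compiled to finite-state machines.

Nomenclature rules are written as a regular grammar, e.g.::

    alkaneStem : 'meth' | 'eth' | 'prop'
    alkane     : alkaneStem 'ane'

One rule per line, ``name : production``; ``|`` is alternation,
juxtaposition is concatenation, postfix ``*`` is Kleene star and ``?``
marks an optional item, ``( )`` group, literals go in single quotes and
``#`` starts a comment.  Rules may reference other rules, and ``$name``
references a dictionary used as a terminal.  Regularity is enforced by
requiring the rule-reference graph to be acyclic (a rule may not
reference itself, directly or indirectly); within that restriction every
reference can be inlined, so each grammar denotes a regular language.

Compilation inlines references, builds a Thompson NFA and determinizes
it by subset construction into a :class:`CharAutomaton`.  For the large
systematic-nomenclature use case a two-level machine is provided: a
master automaton whose transition labels are *other automata*
(:class:`LayeredAutomaton`), keeping global name context separate from
local token matching.

Matching keeps a record of round/square/curly brackets seen: a span is
only reported when the brackets inside it are balanced and well nested,
which a single regular machine cannot itself guarantee.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

__all__ = [
    "GrammarError",
    "NonRegularGrammarError",
    "GrammarRule",
    "Grammar",
    "CharAutomaton",
    "LayeredAutomaton",
    "BracketTracker",
    "parse_grammar",
    "compile_grammar",
    "compile_layered",
    "match_longest",
]

BRACKET_PAIRS = {")": "(", "]": "[", "}": "{"}
OPEN_BRACKETS = frozenset(BRACKET_PAIRS.values())
CLOSE_BRACKETS = frozenset(BRACKET_PAIRS)


class GrammarError(ValueError):
    """Syntax or resolution error in a grammar definition."""


class NonRegularGrammarError(GrammarError):
    """The rule-reference graph contains a cycle: a rule may not
    reference itself, so the grammar is not regular under this dialect."""


# ---------------------------------------------------------------------------
# Expression tree

@dataclass(frozen=True)
class Lit:
    text: str


@dataclass(frozen=True)
class Ref:
    name: str


@dataclass(frozen=True)
class LexRef:
    name: str


@dataclass(frozen=True)
class Cat:
    parts: tuple


@dataclass(frozen=True)
class Alt:
    options: tuple


@dataclass(frozen=True)
class Star:
    inner: object


@dataclass(frozen=True)
class Opt:
    inner: object


@dataclass(frozen=True)
class GrammarRule:
    name: str
    production: object  # expression tree


@dataclass
class Grammar:
    rules: dict[str, GrammarRule]
    root: str
    lexicon_refs: set[str] = field(default_factory=set)

    def rule(self, name: str) -> GrammarRule:
        return self.rules[name]


# ---------------------------------------------------------------------------
# Parsing

def _tokenize(line: str, lineno: int):
    tokens = []
    i = 0
    n = len(line)
    while i < n:
        c = line[i]
        if c.isspace():
            i += 1
        elif c == "#":
            break
        elif c == "'":
            j = line.find("'", i + 1)
            if j == -1:
                raise GrammarError(f"line {lineno}: unterminated literal")
            if j == i + 1:
                raise GrammarError(f"line {lineno}: empty literal")
            tokens.append(("lit", line[i + 1:j]))
            i = j + 1
        elif c in "|*?()":
            tokens.append((c, c))
            i += 1
        elif c == "$":
            j = i + 1
            while j < n and (line[j].isalnum() or line[j] == "_"):
                j += 1
            if j == i + 1:
                raise GrammarError(f"line {lineno}: bare '$'")
            tokens.append(("lexref", line[i + 1:j]))
            i = j
        elif c.isalpha() or c == "_":
            j = i
            while j < n and (line[j].isalnum() or line[j] == "_"):
                j += 1
            tokens.append(("name", line[i:j]))
            i = j
        else:
            raise GrammarError(f"line {lineno}: unexpected character {c!r}")
    return tokens


def _parse_expr(tokens, pos, lineno):
    options = []
    part, pos = _parse_cat(tokens, pos, lineno)
    options.append(part)
    while pos < len(tokens) and tokens[pos][0] == "|":
        part, pos = _parse_cat(tokens, pos + 1, lineno)
        options.append(part)
    if len(options) == 1:
        return options[0], pos
    return Alt(tuple(options)), pos


def _parse_cat(tokens, pos, lineno):
    parts = []
    while pos < len(tokens) and tokens[pos][0] in ("lit", "name", "lexref", "("):
        atom, pos = _parse_atom(tokens, pos, lineno)
        parts.append(atom)
    if not parts:
        raise GrammarError(f"line {lineno}: empty production")
    if len(parts) == 1:
        return parts[0], pos
    return Cat(tuple(parts)), pos


def _parse_atom(tokens, pos, lineno):
    kind, value = tokens[pos]
    if kind == "lit":
        node: object = Lit(value)
        pos += 1
    elif kind == "name":
        node = Ref(value)
        pos += 1
    elif kind == "lexref":
        node = LexRef(value)
        pos += 1
    elif kind == "(":
        node, pos = _parse_expr(tokens, pos + 1, lineno)
        if pos >= len(tokens) or tokens[pos][0] != ")":
            raise GrammarError(f"line {lineno}: missing ')'")
        pos += 1
    else:
        raise GrammarError(f"line {lineno}: unexpected token {value!r}")
    while pos < len(tokens) and tokens[pos][0] in ("*", "?"):
        node = Star(node) if tokens[pos][0] == "*" else Opt(node)
        pos += 1
    return node, pos


def _refs_in(expr) -> set[str]:
    if isinstance(expr, Ref):
        return {expr.name}
    if isinstance(expr, (Cat, Alt)):
        parts = expr.parts if isinstance(expr, Cat) else expr.options
        out: set[str] = set()
        for p in parts:
            out |= _refs_in(p)
        return out
    if isinstance(expr, (Star, Opt)):
        return _refs_in(expr.inner)
    return set()


def _lexrefs_in(expr) -> set[str]:
    if isinstance(expr, LexRef):
        return {expr.name}
    if isinstance(expr, (Cat, Alt)):
        parts = expr.parts if isinstance(expr, Cat) else expr.options
        out: set[str] = set()
        for p in parts:
            out |= _lexrefs_in(p)
        return out
    if isinstance(expr, (Star, Opt)):
        return _lexrefs_in(expr.inner)
    return set()


def parse_grammar(source: str, root: str | None = None,
                  imports: dict[str, GrammarRule] | None = None) -> Grammar:
    """Parse grammar text into a :class:`Grammar`.

    ``root`` defaults to the last rule defined.  ``imports`` supplies
    rules inherited from other grammars.  Raises
    :class:`NonRegularGrammarError` if the rule-reference graph has a
    cycle, and :class:`GrammarError` with a line number for syntax
    problems or unresolved references.
    """
    rules: dict[str, GrammarRule] = dict(imports or {})
    last_name = None
    for lineno, line in enumerate(source.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if ":" not in stripped:
            raise GrammarError(f"line {lineno}: expected 'name : production'")
        name, prod_src = stripped.split(":", 1)
        name = name.strip()
        if not name.replace("_", "").isalnum():
            raise GrammarError(f"line {lineno}: bad rule name {name!r}")
        if name in rules and (imports is None or name not in imports):
            raise GrammarError(f"line {lineno}: duplicate rule {name!r}")
        tokens = _tokenize(prod_src, lineno)
        if not tokens:
            raise GrammarError(f"line {lineno}: empty production")
        expr, pos = _parse_expr(tokens, 0, lineno)
        if pos != len(tokens):
            raise GrammarError(f"line {lineno}: trailing tokens")
        rules[name] = GrammarRule(name, expr)
        last_name = name
    if not rules:
        raise GrammarError("no rules defined")
    root = root or last_name
    if root not in rules:
        raise GrammarError(f"root rule {root!r} not defined")
    # resolution + acyclicity (regularity)
    graph = {n: _refs_in(r.production) for n, r in rules.items()}
    for name, refs in graph.items():
        for ref in refs:
            if ref not in rules:
                raise GrammarError(f"rule {name!r} references undefined rule {ref!r}")
    _check_acyclic(graph)
    lexicon_refs: set[str] = set()
    for r in rules.values():
        lexicon_refs |= _lexrefs_in(r.production)
    return Grammar(rules=rules, root=root, lexicon_refs=lexicon_refs)


def _check_acyclic(graph: dict[str, set[str]]) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in graph}

    def visit(node, path):
        color[node] = GREY
        for nxt in graph[node]:
            if color[nxt] == GREY:
                cycle = " -> ".join(path + [nxt])
                raise NonRegularGrammarError(
                    f"a rule may not reference itself: cycle {cycle}")
            if color[nxt] == WHITE:
                visit(nxt, path + [nxt])
        color[node] = BLACK

    for n in graph:
        if color[n] == WHITE:
            visit(n, [n])


# ---------------------------------------------------------------------------
# NFA construction and determinization

class _NFA:
    def __init__(self):
        self.transitions: list[dict] = []  # state -> {label: set(states)}; label None = eps
        self.start = self._new()
        self.accept = self._new()

    def _new(self) -> int:
        self.transitions.append({})
        return len(self.transitions) - 1

    def add(self, src: int, label, dst: int) -> None:
        self.transitions[src].setdefault(label, set()).add(dst)


def _build_nfa(expr, nfa: _NFA, src: int, dst: int, grammar: Grammar,
               case_insensitive: bool, label_for_lexref) -> None:
    if isinstance(expr, Lit):
        cur = src
        for i, ch in enumerate(expr.text):
            nxt = dst if i == len(expr.text) - 1 else nfa._new()
            if case_insensitive and ch.lower() != ch.upper():
                nfa.add(cur, ch.lower(), nxt)
                nfa.add(cur, ch.upper(), nxt)
            else:
                nfa.add(cur, ch, nxt)
            cur = nxt
    elif isinstance(expr, Ref):
        _build_nfa(grammar.rule(expr.name).production, nfa, src, dst, grammar,
                   case_insensitive, label_for_lexref)
    elif isinstance(expr, LexRef):
        label_for_lexref(expr.name, nfa, src, dst)
    elif isinstance(expr, Cat):
        cur = src
        for i, part in enumerate(expr.parts):
            nxt = dst if i == len(expr.parts) - 1 else nfa._new()
            _build_nfa(part, nfa, cur, nxt, grammar, case_insensitive, label_for_lexref)
            cur = nxt
    elif isinstance(expr, Alt):
        for option in expr.options:
            _build_nfa(option, nfa, src, dst, grammar, case_insensitive, label_for_lexref)
    elif isinstance(expr, Star):
        mid = nfa._new()
        nfa.add(src, None, mid)
        _build_nfa(expr.inner, nfa, mid, mid, grammar, case_insensitive, label_for_lexref)
        nfa.add(mid, None, dst)
    elif isinstance(expr, Opt):
        nfa.add(src, None, dst)
        _build_nfa(expr.inner, nfa, src, dst, grammar, case_insensitive, label_for_lexref)
    else:  # pragma: no cover
        raise TypeError(f"unknown expression node {expr!r}")


def _eps_closure(nfa: _NFA, states: frozenset[int]) -> frozenset[int]:
    stack = list(states)
    seen = set(states)
    while stack:
        s = stack.pop()
        for t in nfa.transitions[s].get(None, ()):
            if t not in seen:
                seen.add(t)
                stack.append(t)
    return frozenset(seen)


def _determinize(nfa: _NFA) -> "CharAutomaton":
    start = _eps_closure(nfa, frozenset([nfa.start]))
    index = {start: 0}
    transitions: list[dict] = [{}]
    accepting: set[int] = set()
    if nfa.accept in start:
        accepting.add(0)
    queue = [start]
    while queue:
        cur = queue.pop()
        cur_id = index[cur]
        moves: dict = {}
        for s in cur:
            for label, dsts in nfa.transitions[s].items():
                if label is None:
                    continue
                moves.setdefault(label, set()).update(dsts)
        for label, dsts in moves.items():
            closure = _eps_closure(nfa, frozenset(dsts))
            if closure not in index:
                index[closure] = len(transitions)
                transitions.append({})
                if nfa.accept in closure:
                    accepting.add(index[closure])
                queue.append(closure)
            transitions[cur_id][label] = index[closure]
    return CharAutomaton(transitions=transitions, start=0, accepting=accepting)


@dataclass
class BracketTracker:
    """Stack of open brackets seen inside the current candidate match."""

    stack: list[str] = field(default_factory=list)
    valid: bool = True  # becomes False on an ill-nested close, permanently

    def feed(self, ch: str) -> None:
        if not self.valid:
            return
        if ch in OPEN_BRACKETS:
            self.stack.append(ch)
        elif ch in CLOSE_BRACKETS:
            if not self.stack or self.stack[-1] != BRACKET_PAIRS[ch]:
                self.valid = False
            else:
                self.stack.pop()

    @property
    def balanced(self) -> bool:
        return self.valid and not self.stack


@dataclass
class CharAutomaton:
    """Deterministic finite automaton over characters.

    ``transitions[state]`` maps a character to the next state; all
    states are reachable from ``start`` by construction (subset
    construction only creates reachable states).
    """

    transitions: list[dict]
    start: int
    accepting: set[int]

    def accepts(self, text: str) -> bool:
        state = self.start
        for ch in text:
            state = self.transitions[state].get(ch)
            if state is None:
                return False
        return state in self.accepting

    def match_ends(self, text: str, start: int = 0, track_brackets: bool = True):
        """Yield end offsets of every accepted prefix; with
        ``track_brackets`` only bracket-balanced, well-nested prefixes
        are reported."""
        state = self.start
        tracker = BracketTracker()
        if state in self.accepting:
            yield start
        for i in range(start, len(text)):
            state = self.transitions[state].get(text[i])
            if state is None:
                return
            tracker.feed(text[i])
            if state in self.accepting and (not track_brackets or tracker.balanced):
                yield i + 1

    def match_longest(self, text: str, start: int = 0) -> tuple[int, int] | None:
        """Longest accepted prefix from ``start`` whose brackets are
        balanced and well nested; ``None`` if there is none (an empty
        match is not reported as a span)."""
        best = None
        for end in self.match_ends(text, start):
            if end > start:
                best = (start, end)
        return best

    # -- serialization (portable cache format) --
    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "accepting": sorted(self.accepting),
            "transitions": [
                {ch: dst for ch, dst in sorted(t.items())} for t in self.transitions
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False)

    @classmethod
    def from_dict(cls, d: dict) -> "CharAutomaton":
        return cls(
            transitions=[dict(t) for t in d["transitions"]],
            start=d["start"],
            accepting=set(d["accepting"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "CharAutomaton":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_terms(cls, terms, case_insensitive: bool = False) -> "CharAutomaton":
        """Build a DFA accepting exactly the given set of strings (a trie)."""
        transitions: list[dict] = [{}]
        accepting: set[int] = set()
        for term in terms:
            state = 0
            for ch in term:
                variants = (ch,)
                if case_insensitive and ch.lower() != ch.upper():
                    variants = (ch.lower(), ch.upper())
                nxt = transitions[state].get(variants[0])
                if nxt is None:
                    transitions.append({})
                    nxt = len(transitions) - 1
                for v in variants:
                    transitions[state][v] = nxt
                state = nxt
            accepting.add(state)
        return cls(transitions=transitions, start=0, accepting=accepting)

    def enumerate_language(self, max_len: int, limit: int = 10_000_000):
        """Yield every accepted string of length ≤ max_len (DFS over paths)."""
        count = 0

        def dfs(state: int, prefix: str):
            nonlocal count
            if state in self.accepting:
                count += 1
                if count > limit:
                    raise RuntimeError("language enumeration limit exceeded")
                yield prefix
            if len(prefix) == max_len:
                return
            for ch in sorted(self.transitions[state]):
                yield from dfs(self.transitions[state][ch], prefix + ch)

        yield from dfs(self.start, "")


def compile_grammar(g: Grammar, case_insensitive: bool = False,
                    lexicons: dict | None = None) -> CharAutomaton:
    """Compile a grammar to a deterministic automaton.

    Lexicon references (``$name``) are inlined as the alternation of the
    lexicon's terms; ``lexicons`` maps name → iterable of terms or an
    object with a ``terms`` attribute.
    """
    lexicons = lexicons or {}

    def inline_lexref(name: str, nfa: _NFA, src: int, dst: int) -> None:
        if name not in lexicons:
            raise GrammarError(f"unresolved lexicon reference ${name}")
        terms = getattr(lexicons[name], "terms", lexicons[name])
        for term in terms:
            _build_nfa(Lit(term), nfa, src, dst, g, case_insensitive, inline_lexref)

    nfa = _NFA()
    _build_nfa(g.rule(g.root).production, nfa, nfa.start, nfa.accept, g,
               case_insensitive, inline_lexref)
    return _determinize(nfa)


@dataclass
class LayeredAutomaton:
    """Two-level machine: a master DFA whose transition labels name
    sub-machines that consume the actual characters.

    The master keeps track of overall (nomenclature) context while the
    sub-machines match text, so one sub-machine can be reused in
    contexts that allow different continuations.
    """

    master: CharAutomaton  # labels are sub-machine names, not characters
    sub_machines: dict[str, CharAutomaton]

    def __post_init__(self):
        for t in self.master.transitions:
            for label in t:
                if label not in self.sub_machines:
                    raise GrammarError(f"unresolved sub-machine {label!r}")

    def match_ends(self, text: str, start: int = 0):
        """Yield end offsets of accepted, bracket-valid prefixes.

        Dynamic programming over (position, master state): at each
        reachable configuration every outgoing sub-machine is run from
        that position, and each of its accepted prefixes advances the
        master by one labelled transition.  Bracket validity is judged
        globally over the whole candidate span, not per sub-match.
        """
        tracker_ok: list[bool] = [True]
        tracker = BracketTracker()
        for i in range(start, len(text)):
            tracker.feed(text[i])
            tracker_ok.append(tracker.balanced)

        states_at: dict[int, set[int]] = {start: {self.master.start}}
        heap = [start]
        done: set[int] = set()
        yielded: list[int] = []
        while heap:
            pos = heapq.heappop(heap)
            if pos in done:
                continue
            done.add(pos)
            states = states_at[pos]
            if pos > start and tracker_ok[pos - start] \
                    and states & self.master.accepting:
                yielded.append(pos)
            for state in states:
                for label, nxt_master in self.master.transitions[state].items():
                    sub = self.sub_machines[label]
                    for end in sub.match_ends(text, pos, track_brackets=False):
                        if end == pos:
                            continue  # no empty sub-matches: guarantees progress
                        bucket = states_at.setdefault(end, set())
                        if nxt_master not in bucket:
                            bucket.add(nxt_master)
                            heapq.heappush(heap, end)
        yield from yielded

    def match_longest(self, text: str, start: int = 0) -> tuple[int, int] | None:
        best = None
        for end in self.match_ends(text, start):
            best = (start, end)
        return best

    def accepts(self, text: str) -> bool:
        return any(end == len(text) for end in self.match_ends(text, 0)) \
            or (text == "" and self.master.start in self.master.accepting)


def compile_layered(master: Grammar, subs: dict) -> LayeredAutomaton:
    """Compile ``master`` over the alphabet of sub-machine labels.

    ``subs`` maps a name to a Grammar, a compiled CharAutomaton, or an
    iterable of terms (a dictionary used as a terminal).  In the master
    grammar both rule references that are not locally defined and
    ``$name`` references resolve to sub-machines.
    """
    compiled: dict[str, CharAutomaton] = {}
    for name, sub in subs.items():
        if isinstance(sub, CharAutomaton):
            compiled[name] = sub
        elif isinstance(sub, Grammar):
            compiled[name] = compile_grammar(sub)
        else:
            terms = getattr(sub, "terms", sub)
            compiled[name] = CharAutomaton.from_terms(terms)

    # In the master, a LexRef or a Ref to an undefined rule is a sub-machine
    # terminal: encode it as a single NFA transition labelled by its name.
    # Labels here are sub-machine names; the DFA alphabet is those names.
    def label_lexref(name: str, nfa: _NFA, src: int, dst: int) -> None:
        if name not in compiled:
            raise GrammarError(f"unresolved sub-machine {name!r}")
        nfa.add(src, name, dst)

    # rewrite Refs that point at sub-machines into LexRefs
    def rewrite(expr):
        if isinstance(expr, Ref) and expr.name not in master.rules:
            return LexRef(expr.name)
        if isinstance(expr, Ref) and expr.name in compiled \
                and expr.name not in master.rules:
            return LexRef(expr.name)
        if isinstance(expr, Cat):
            return Cat(tuple(rewrite(p) for p in expr.parts))
        if isinstance(expr, Alt):
            return Alt(tuple(rewrite(o) for o in expr.options))
        if isinstance(expr, Star):
            return Star(rewrite(expr.inner))
        if isinstance(expr, Opt):
            return Opt(rewrite(expr.inner))
        return expr

    rewritten = Grammar(
        rules={n: GrammarRule(n, rewrite(r.production)) for n, r in master.rules.items()},
        root=master.root,
        lexicon_refs=master.lexicon_refs,
    )
    nfa = _NFA()
    _build_nfa(rewritten.rule(rewritten.root).production, nfa, nfa.start,
               nfa.accept, rewritten, False, label_lexref)
    master_dfa = _determinize(nfa)
    return LayeredAutomaton(master=master_dfa, sub_machines=compiled)


def match_longest(a, text: str, start: int = 0) -> tuple[int, int] | None:
    """Longest accepted, bracket-valid span at ``start`` (module-level
    convenience working for both automaton kinds)."""
    if start > len(text):
        raise IndexError(f"start {start} beyond end of text")
    return a.match_longest(text, start)
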