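"""Weighted spelling correction against an automaton.

Given a token that no grammar or dictionary accepts, find the cheapest
sequence of edits that turns it into a string the target automaton
*does* accept.  Generic edits — insertion, deletion, substitution and
adjacent transposition — carry a unit cost and are limited by a
per-resource budget.  *Parameterized* edits are known error patterns
(OCR confusions like ``rn``/``m`` or ``l``/``1``, the common ``floro``
for ``fluoro`` typo, an erroneous space, a comma typed for a period, a
missing hyphen) and carry a reduced cost; they do not count against the
generic-edit budget, so a resource can be configured to allow *only*
known error classes by setting that budget to zero.

The search is uniform-cost (Dijkstra) over states
``(automaton state, candidate position, generic edits used)``; the
result is therefore a minimum-total-cost correction.  Ties are broken
by fewest edits, then earliest edit position, then lexicographically
smallest corrected string.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .grammar import CharAutomaton

__all__ = [
    "EditCostModel",
    "CorrectionConfig",
    "CorrectionResult",
    "Edit",
    "NOT_APPLICABLE",
    "correct_against",
]


@dataclass(frozen=True)
class Edit:
    """One applied edit: ``kind`` is insert/delete/substitute/transpose
    or param:<src>-><dst>; ``pos`` is the offset in the input candidate."""

    kind: str
    pos: int
    original: str
    replacement: str


#: (pattern, replacement, cost) triples; pattern may be empty (pure
#: insertion of the replacement) and replacement may be empty (deletion).
DEFAULT_PARAMETERIZED: tuple[tuple[str, str, float], ...] = (
    ("rn", "m", 0.3),
    ("m", "rn", 0.3),
    ("l", "1", 0.3),
    ("1", "l", 0.3),
    ("O", "0", 0.3),
    ("0", "O", 0.3),
    ("floro", "fluoro", 0.3),
    (" ", "", 0.3),      # erroneous space
    (",", ".", 0.3),     # comma instead of a period
    ("", "-", 0.3),      # missing hyphen
)


@dataclass(frozen=True)
class EditCostModel:
    """Costs for generic edits plus the parameterized error patterns.

    All costs must be positive and each parameterized cost lower than
    the corresponding generic operation would charge.
    """

    insertion: float = 1.0
    deletion: float = 1.0
    substitution: float = 1.0
    transposition: float = 1.0
    parameterized: tuple[tuple[str, str, float], ...] = DEFAULT_PARAMETERIZED

    def __post_init__(self):
        base = (self.insertion, self.deletion, self.substitution, self.transposition)
        if any(c <= 0 for c in base):
            raise ValueError("base edit costs must be positive")
        for src, dst, cost in self.parameterized:
            if cost <= 0 or cost >= min(base):
                raise ValueError(
                    f"parameterized cost for {src!r}->{dst!r} must be in (0, base)")
            if not src and not dst:
                raise ValueError("parameterized edit must change something")


@dataclass(frozen=True)
class CorrectionConfig:
    """Per-resource correction policy: whether to correct at all, how
    many generic (unparameterized) edits to allow, and how long a
    candidate must be before correction is attempted."""

    enabled: bool = True
    max_unparameterized_edits: int = 1
    min_entity_length: int = 4

    def __post_init__(self):
        if self.max_unparameterized_edits < 0 or self.min_entity_length < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class CorrectionResult:
    corrected: str
    edits: tuple[Edit, ...]
    total_cost: float


class _NotApplicable:
    """Correction was not attempted (disabled, or candidate too short);
    distinct from 'attempted but nothing found' (None)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __bool__(self):
        return False

    def __repr__(self):
        return "NOT_APPLICABLE"


NOT_APPLICABLE = _NotApplicable()

# safety valve for pathological automata; toy resources stay far below it
_MAX_EXPANSIONS = 500_000


def _feed(a: CharAutomaton, state: int, text: str) -> int | None:
    for ch in text:
        state = a.transitions[state].get(ch)
        if state is None:
            return None
    return state


def correct_against(a: CharAutomaton, candidate: str, model: EditCostModel,
                    cfg: CorrectionConfig):
    """Cheapest correction of ``candidate`` into the language of ``a``.

    Returns a :class:`CorrectionResult` (zero edits, cost 0 if the
    candidate is already accepted), ``None`` if no accepted string is
    reachable within the budget, or :data:`NOT_APPLICABLE` when the
    config disables correction or the candidate is too short.
    """
    if not cfg.enabled or len(candidate) < cfg.min_entity_length:
        return NOT_APPLICABLE

    n = len(candidate)
    # priority: cost, edit count, edit positions, emitted string; a
    # running counter breaks any remaining tie deterministically
    counter = 0
    heap = [(0.0, 0, (), "", 0, a.start, 0, 0, ())]
    settled: set[tuple[int, int, int]] = set()
    expansions = 0
    while heap:
        cost, n_edits, positions, emitted, _c, state, pos, used, edits = \
            heapq.heappop(heap)
        key = (state, pos, used)
        if key in settled:
            continue
        settled.add(key)
        if pos == n and state in a.accepting:
            return CorrectionResult(emitted, tuple(edits), cost)
        expansions += 1
        if expansions > _MAX_EXPANSIONS:
            return None

        def push(ncost, nstate, npos, nused, edit: Edit | None, add: str):
            nonlocal counter
            if (nstate, npos, nused) in settled:
                return
            counter += 1
            if edit is None:
                heapq.heappush(heap, (ncost, n_edits, positions, emitted + add,
                                      counter, nstate, npos, nused, edits))
            else:
                heapq.heappush(heap, (ncost, n_edits + 1, positions + (edit.pos,),
                                      emitted + add, counter, nstate, npos, nused,
                                      edits + (edit,)))

        # exact character match
        if pos < n:
            nxt = a.transitions[state].get(candidate[pos])
            if nxt is not None:
                push(cost, nxt, pos + 1, used, None, candidate[pos])

        # parameterized edits (not counted against the generic budget)
        for src, dst, pcost in model.parameterized:
            if src and not candidate.startswith(src, pos):
                continue
            nstate = _feed(a, state, dst)
            if nstate is None:
                continue
            if not src and not dst:
                continue
            edit = Edit(f"param:{src or 'ε'}->{dst or 'ε'}", pos, src, dst)
            # treat param edits as edits for tie-breaking but not budget
            push(cost + pcost, nstate, pos + len(src), used, edit, dst)

        if used < cfg.max_unparameterized_edits:
            # deletion of the current candidate character
            if pos < n:
                push(cost + model.deletion, state, pos + 1, used + 1,
                     Edit("delete", pos, candidate[pos], ""), "")
            # substitution / insertion over every outgoing character
            for ch, nxt in a.transitions[state].items():
                if pos < n and ch != candidate[pos]:
                    push(cost + model.substitution, nxt, pos + 1, used + 1,
                         Edit("substitute", pos, candidate[pos], ch), ch)
                push(cost + model.insertion, nxt, pos, used + 1,
                     Edit("insert", pos, "", ch), ch)
            # transposition of two adjacent candidate characters
            if pos + 1 < n and candidate[pos] != candidate[pos + 1]:
                nstate = _feed(a, state, candidate[pos + 1] + candidate[pos])
                if nstate is not None:
                    push(cost + model.transposition, nstate, pos + 2, used + 1,
                         Edit("transpose", pos, candidate[pos:pos + 2],
                              candidate[pos + 1] + candidate[pos]),
                         candidate[pos + 1] + candidate[pos])
    return None
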