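"""Grammar parsing, DFA compilation, layered machines, bracket validity.

Each fixture grammar is checked against an independently written oracle
(a regex or a plain enumeration built from the printed rules, not from
the compiler) by complete two-sided language comparison up to a length
bound plus random-string agreement sampling.
"""

import itertools
import random
import re

import pytest

from chemtagger.fixtures import (ALKANE_GRAMMAR, CAS_GRAMMAR, CID_GRAMMAR,
                                 REGISTRY_GRAMMAR, SUM_FORMULA_GRAMMAR)
from chemtagger.grammar import (CharAutomaton, GrammarError,
                                NonRegularGrammarError, compile_grammar,
                                compile_layered, match_longest, parse_grammar)

# ---------------------------------------------------------------------------
# independent oracles, written from the printed rules

ALKANE_STEMS = ["meth", "eth", "prop", "but", "pent", "hex", "hept", "oct",
                "non", "dec"]
ALKANE_LANGUAGE = {stem + "ane" for stem in ALKANE_STEMS}

CID_RE = re.compile(r"CID:[1-9][0-9]*")
CAS_RE = re.compile(r"[0-9]{2,7}-[0-9]{2}-[0-9]")
FORMULA_RE = re.compile(
    r"(?:(?:Cl|Ca|Cu|Br|Na|Mg|Fe|Zn|Mn|Al|Si|C|H|N|O|S|P|F|I|K|B)"
    r"(?:[1-9][0-9]*)?)+")
REGISTRY_RE = re.compile(r"[A-Z]{2,4}[1-9][0-9]{3,7}")


def _oracle_cid_strings(max_len):
    for n_digits in range(1, max_len - 4 + 1):
        for first in "123456789":
            for rest in itertools.product("0123456789", repeat=n_digits - 1):
                yield "CID:" + first + "".join(rest)


def _oracle_cas_strings(max_len):
    digits = "0123456789"
    for n in range(2, 8):
        if n + 5 > max_len:
            break
        for head in itertools.product(digits, repeat=n):
            for mid in itertools.product(digits, repeat=2):
                for last in digits:
                    yield "".join(head) + "-" + "".join(mid) + "-" + last


# ---------------------------------------------------------------------------
# parsing

def test_parse_cid_grammar_structure():
    g = parse_grammar(CID_GRAMMAR)
    assert set(g.rules) == {"Digit1to9", "Digit", "Cid"}
    assert g.root == "Cid"


def test_parse_alkane_grammar_structure():
    g = parse_grammar(ALKANE_GRAMMAR)
    assert set(g.rules) == {"alkaneStem", "alkane"}


@pytest.mark.parametrize("source", [
    "X : 'a' X",                     # direct self-reference
    "A : B\nB : 'x' A",              # mutual recursion
])
def test_self_reference_is_non_regular(source):
    with pytest.raises(NonRegularGrammarError):
        parse_grammar(source)


@pytest.mark.parametrize("source,fragment", [
    ("A : 'a' |", "empty"),
    ("A 'a'", "name : production"),
    ("A : 'a' B", "undefined"),
    ("A : 'a'\nA : 'b'", "duplicate"),
    ("A : ''", "literal"),
])
def test_syntax_errors_are_reported(source, fragment):
    with pytest.raises(GrammarError) as err:
        parse_grammar(source)
    assert fragment in str(err.value)


# ---------------------------------------------------------------------------
# compiled automata vs oracles

@pytest.fixture(scope="module")
def automata():
    return {
        "cid": compile_grammar(parse_grammar(CID_GRAMMAR)),
        "alkane": compile_grammar(parse_grammar(ALKANE_GRAMMAR)),
        "cas": compile_grammar(parse_grammar(CAS_GRAMMAR)),
        "formula": compile_grammar(parse_grammar(SUM_FORMULA_GRAMMAR)),
        "registry": compile_grammar(parse_grammar(REGISTRY_GRAMMAR)),
    }


def test_cid_examples(automata):
    a = automata["cid"]
    assert a.accepts("CID:42")
    assert not a.accepts("CID:0")      # first digit excludes zero
    assert not a.accepts("CID:")


def test_alkane_examples(automata):
    a = automata["alkane"]
    assert a.accepts("ethane")
    assert not a.accepts("ethan")


def test_alkane_language_equals_enumeration_oracle(automata):
    accepted = set(automata["alkane"].enumerate_language(10))
    assert accepted == ALKANE_LANGUAGE


def test_cas_example(automata):
    assert automata["cas"].accepts("2634-33-5")


def test_registry_example(automata):
    assert automata["registry"].accepts("GSK2248761")
    assert REGISTRY_RE.fullmatch("GSK2248761")


@pytest.mark.parametrize("name,oracle_re,dfa_bound", [
    ("cid", CID_RE, 8),
    ("cas", CAS_RE, 8),
    ("formula", FORMULA_RE, 4),
])
def test_dfa_language_subset_of_oracle(automata, name, oracle_re, dfa_bound):
    """Every string the DFA accepts (up to a bound) matches the oracle."""
    count = 0
    for s in automata[name].enumerate_language(dfa_bound):
        assert oracle_re.fullmatch(s), s
        count += 1
    assert count > 0


@pytest.mark.parametrize("name,oracle_re", [
    ("formula", FORMULA_RE),
    ("registry", REGISTRY_RE),
])
def test_dfa_samples_match_oracle(automata, name, oracle_re):
    """Longer accepted strings (random DFA walks) also match the oracle."""
    rng = random.Random(11)
    a = automata[name]
    for _ in range(2000):
        state, out = a.start, []
        while len(out) < 12:
            if state in a.accepting and out and rng.random() < 0.35:
                break
            choices = sorted(a.transitions[state])
            if not choices:
                break
            ch = rng.choice(choices)
            out.append(ch)
            state = a.transitions[state][ch]
        if state in a.accepting and out:
            assert oracle_re.fullmatch("".join(out)), "".join(out)


def test_oracle_language_subset_of_dfa_cid(automata):
    a = automata["cid"]
    for s in _oracle_cid_strings(8):
        assert a.accepts(s), s


def test_oracle_language_subset_of_dfa_cas(automata):
    a = automata["cas"]
    n = 0
    for s in _oracle_cas_strings(7):
        assert a.accepts(s), s
        n += 1
    assert n == 10 ** 5  # all two-digit-head CAS shapes


@pytest.mark.parametrize("name,oracle_re,alphabet", [
    ("cid", CID_RE, "CID:0123456789"),
    ("cas", CAS_RE, "0123456789-"),
    ("formula", FORMULA_RE, "CHNOSPFIKBclaurgezn0123456789"),
    ("registry", REGISTRY_RE, "ABCGKSXZ0123456789"),
])
def test_random_string_agreement(automata, name, oracle_re, alphabet):
    rng = random.Random(42)
    a = automata[name]
    for _ in range(5000):
        s = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 10)))
        assert a.accepts(s) == bool(oracle_re.fullmatch(s)), s


def test_scanning_is_deterministic(automata):
    text = "take CID:123 and 2634-33-5 with C20H25NO6 twice"
    for a in automata.values():
        spans1 = [match_longest(a, text, i) for i in range(len(text))]
        spans2 = [match_longest(a, text, i) for i in range(len(text))]
        assert spans1 == spans2


def test_longest_match(automata):
    assert match_longest(automata["cid"], "CID:1234x", 0) == (0, 8)
    # no longer accepted, bracket-valid prefix exists
    a = automata["cid"]
    span = a.match_longest("CID:1234", 0)
    assert span == (0, 8)
    for end in a.match_ends("CID:1234", 0):
        assert end <= span[1]


def test_match_at_end_of_text(automata):
    assert match_longest(automata["cid"], "CID:5", 5) is None
    with pytest.raises(IndexError):
        match_longest(automata["cid"], "x", 9)


# ---------------------------------------------------------------------------
# bracket validity

def test_unbalanced_bracket_blocks_match():
    lex = CharAutomaton.from_terms({"2(3H)-furanone"})
    assert lex.match_longest("2(3H-furanone", 0) is None
    assert lex.match_longest("2(3H)-furanone", 0) == (0, 14)


def test_random_bracket_strings_never_yield_invalid_spans():
    """Longest-match spans always have balanced, well-nested brackets."""
    rng = random.Random(7)
    alphabet = "ab()[]{}"
    terms = set()
    while len(terms) < 30:
        terms.add("".join(rng.choice(alphabet) for _ in range(rng.randint(2, 8))))
    a = CharAutomaton.from_terms(terms)
    pairs = {")": "(", "]": "[", "}": "{"}
    for _ in range(2000):
        text = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 20)))
        span = a.match_longest(text, 0)
        if span is None:
            continue
        stack = []
        for ch in text[span[0]:span[1]]:
            if ch in "([{":
                stack.append(ch)
            elif ch in pairs:
                assert stack and stack[-1] == pairs[ch], (text, span)
                stack.pop()
        assert not stack, (text, span)


# ---------------------------------------------------------------------------
# layered automata

@pytest.fixture(scope="module")
def layered_name():
    master = parse_grammar("name : $substituent* $parent")
    return compile_layered(master, {
        "substituent": {"ethyl", "methyl"},
        "parent": {"benzene"},
    })


def test_layered_accepts_composed_names(layered_name):
    assert layered_name.accepts("ethylbenzene")
    assert layered_name.accepts("methylethylbenzene")
    assert layered_name.accepts("benzene")
    assert not layered_name.accepts("ethyl")
    assert not layered_name.accepts("benzeneethyl")


def test_layered_reuses_submachine_in_ester_context(layered_name):
    # the same substituent machine serves a different master context
    master = parse_grammar("ester : $acid $space $substituent $space $esterword")
    ester = compile_layered(master, {
        "acid": {"acetic acid", "benzoic acid"},
        "substituent": {"ethyl", "methyl"},
        "space": {" "},
        "esterword": {"ester"},
    })
    assert ester.accepts("acetic acid ethyl ester")
    assert not ester.accepts("acetic acid ester")
    assert layered_name.accepts("ethylbenzene")  # unchanged


def test_degenerate_layering_equals_submachine():
    master = parse_grammar("root : $only")
    sub_terms = {"alpha", "beta", "gamma"}
    layered = compile_layered(master, {"only": sub_terms})
    sub = CharAutomaton.from_terms(sub_terms)
    for s in ["alpha", "beta", "gamma", "alphabeta", "alph", ""]:
        assert layered.accepts(s) == sub.accepts(s)


def test_layered_equals_flattened_language():
    layered_master = parse_grammar("name : $substituent* $parent")
    layered = compile_layered(layered_master, {
        "substituent": {"ethyl", "methyl"},
        "parent": {"benzene"},
    })
    flat = compile_grammar(
        parse_grammar("""
sub : 'ethyl' | 'methyl'
name : sub* 'benzene'
"""))
    rng = random.Random(3)
    # flattened-side enumeration + random strings, both directions
    for s in flat.enumerate_language(17):
        assert layered.accepts(s), s
    pieces = ["ethyl", "methyl", "benzene", "eth", "yl", ""]
    for _ in range(300):
        s = "".join(rng.choice(pieces) for _ in range(rng.randint(0, 3)))
        assert layered.accepts(s) == flat.accepts(s), s


def test_layered_longest_match():
    master = parse_grammar("name : $substituent* $parent")
    layered = compile_layered(master, {
        "substituent": {"ethyl", "methyl"},
        "parent": {"benzene"},
    })
    assert layered.match_longest("ethylbenzene and more", 0) == (0, 12)
    assert layered.match_longest("xylene", 0) is None


def test_layered_unresolved_submachine():
    master = parse_grammar("name : $nosuch")
    with pytest.raises(GrammarError):
        compile_layered(master, {"other": {"x"}})


# ---------------------------------------------------------------------------
# serialization

def test_automaton_json_round_trip(automata):
    a = automata["cas"]
    b = CharAutomaton.from_json(a.to_json())
    for s in ["2634-33-5", "12-34-5", "1-23-4", "999999-99-9"]:
        assert a.accepts(s) == b.accepts(s)
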