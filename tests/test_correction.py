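"""Spelling correction: optimality against a brute-force oracle,
parameterized-error budgets, tie-breaking."""

import random

import pytest

from chemtagger.correction import (NOT_APPLICABLE, CorrectionConfig,
                                   EditCostModel, correct_against)
from chemtagger.grammar import CharAutomaton, compile_grammar, parse_grammar

MODEL = EditCostModel()
CFG1 = CorrectionConfig(enabled=True, max_unparameterized_edits=1,
                        min_entity_length=4)
CFG2 = CorrectionConfig(enabled=True, max_unparameterized_edits=2,
                        min_entity_length=4)
CFG0 = CorrectionConfig(enabled=True, max_unparameterized_edits=0,
                        min_entity_length=4)


# ---------------------------------------------------------------------------
# independent oracle: DP weighted edit distance candidate -> term with the
# same base + parameterized moves and the same generic-edit budget

def oracle_distance(candidate: str, term: str, model: EditCostModel,
                    budget: int) -> float | None:
    INF = float("inf")
    n, m = len(candidate), len(term)
    # dp[i][j][k] = min cost turning candidate[:i] into term[:j] with k edits
    dp = [[[INF] * (budget + 1) for _ in range(m + 1)] for _ in range(n + 1)]
    dp[0][0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            for k in range(budget + 1):
                cur = dp[i][j][k]
                if cur == INF:
                    continue
                if i < n and j < m and candidate[i] == term[j]:
                    dp[i + 1][j + 1][k] = min(dp[i + 1][j + 1][k], cur)
                if k < budget:
                    if i < n and j < m:
                        dp[i + 1][j + 1][k + 1] = min(
                            dp[i + 1][j + 1][k + 1], cur + model.substitution)
                    if i < n:
                        dp[i + 1][j][k + 1] = min(dp[i + 1][j][k + 1],
                                                  cur + model.deletion)
                    if j < m:
                        dp[i][j + 1][k + 1] = min(dp[i][j + 1][k + 1],
                                                  cur + model.insertion)
                    if i + 1 < n and j + 1 < m and candidate[i] == term[j + 1] \
                            and candidate[i + 1] == term[j] \
                            and candidate[i] != candidate[i + 1]:
                        dp[i + 2][j + 2][k + 1] = min(
                            dp[i + 2][j + 2][k + 1], cur + model.transposition)
                for src, dst, cost in model.parameterized:
                    if candidate.startswith(src, i) and term.startswith(dst, j) \
                            and (src or dst):
                        ni, nj = i + len(src), j + len(dst)
                        dp[ni][nj][k] = min(dp[ni][nj][k], cur + cost)
    best = min(dp[n][m])
    return None if best == INF else best


def oracle_best(candidate: str, terms, model: EditCostModel,
                budget: int) -> float | None:
    costs = [oracle_distance(candidate, t, model, budget) for t in terms]
    costs = [c for c in costs if c is not None]
    return min(costs) if costs else None


# ---------------------------------------------------------------------------

def test_known_typo_floro():
    g = parse_grammar("""
halo : 'fluoro' | 'chloro'
name : halo 'benzene'
""")
    a = compile_grammar(g)
    r = correct_against(a, "florobenzene", MODEL, CFG0)
    assert r is not None and r is not NOT_APPLICABLE
    assert r.corrected == "fluorobenzene"
    assert r.total_cost == pytest.approx(0.3)
    assert all(e.kind.startswith("param:") for e in r.edits)


def test_already_accepted_costs_zero():
    a = CharAutomaton.from_terms({"ethanol"})
    r = correct_against(a, "ethanol", MODEL, CFG1)
    assert r.corrected == "ethanol"
    assert r.edits == () and r.total_cost == 0.0


def test_tie_break_prefers_lexicographically_smallest():
    a = CharAutomaton.from_terms({"ethanol", "ethanal"})
    r = correct_against(a, "ethanil", MODEL, CFG1)
    # both targets are one substitution at position 5; smallest string wins
    assert r.corrected == "ethanal"
    assert r.total_cost == pytest.approx(
        oracle_best("ethanil", {"ethanol", "ethanal"}, MODEL, 1))


def test_zero_budget_blocks_generic_edits():
    a = CharAutomaton.from_terms({"ethanol"})
    assert correct_against(a, "ethanil", MODEL, CFG0) is None
    # but parameterized errors still work with zero generic budget
    r = correct_against(a, "ethano1", MODEL, CFG0)
    assert r.corrected == "ethanol"


def test_disabled_and_too_short_are_distinct_from_not_found():
    a = CharAutomaton.from_terms({"ethanol"})
    off = CorrectionConfig(enabled=False)
    assert correct_against(a, "ethanil", MODEL, off) is NOT_APPLICABLE
    assert correct_against(a, "eth", MODEL, CFG1) is NOT_APPLICABLE
    assert correct_against(a, "zzzzzzz", MODEL, CFG1) is None


def test_corrected_string_is_always_accepted():
    rng = random.Random(5)
    terms = {"aspirin", "warfarin", "morphine", "caffeine", "codeine"}
    a = CharAutomaton.from_terms(terms)
    for _ in range(200):
        t = rng.choice(sorted(terms))
        i = rng.randrange(len(t))
        cand = t[:i] + rng.choice("abcdefghijklmnopqrstuvwxyz") + t[i + 1:]
        r = correct_against(a, cand, MODEL, CFG2)
        if r not in (None, NOT_APPLICABLE):
            assert a.accepts(r.corrected)
            generic = [e for e in r.edits if not e.kind.startswith("param:")]
            assert len(generic) <= CFG2.max_unparameterized_edits


@pytest.mark.parametrize("budget_cfg", [CFG0, CFG1, CFG2])
def test_optimality_against_oracle(budget_cfg):
    """Search cost equals exhaustive DP minimization over the lexicon."""
    rng = random.Random(99)
    terms = sorted({
        "aspirin", "warfarin", "morphine", "caffeine", "codeine", "ethanol",
        "ethanal", "methanol", "toluene", "benzene", "glucose", "fructose",
        "cisplatin", "nicotine", "quinine", "taurine", "serine", "alanine",
    })
    a = CharAutomaton.from_terms(set(terms))
    budget = budget_cfg.max_unparameterized_edits
    n_checked = 0
    for _ in range(200):
        base = rng.choice(terms)
        cand = list(base)
        for _e in range(rng.randint(1, 2)):
            op = rng.choice("sdit")
            i = rng.randrange(len(cand))
            if op == "s":
                cand[i] = rng.choice("abcdefghijklmnopqrstuvwxyz1")
            elif op == "d" and len(cand) > 4:
                del cand[i]
            elif op == "i":
                cand.insert(i, rng.choice("abcdefghijklmnopqrstuvwxyz"))
            elif op == "t" and i + 1 < len(cand):
                cand[i], cand[i + 1] = cand[i + 1], cand[i]
        candidate = "".join(cand)
        if len(candidate) < budget_cfg.min_entity_length:
            continue
        got = correct_against(a, candidate, MODEL, budget_cfg)
        want = oracle_best(candidate, terms, MODEL, budget)
        if got in (None, NOT_APPLICABLE):
            assert want is None, (candidate, want)
        else:
            assert got.total_cost == pytest.approx(want), candidate
            n_checked += 1
    # with a zero generic budget only parameterized errors are reachable,
    # so far fewer random perturbations admit any correction at all
    assert n_checked > (20 if budget else 3)


def test_budget_monotonicity():
    rng = random.Random(17)
    terms = {"aspirin", "morphine", "caffeine"}
    a = CharAutomaton.from_terms(terms)
    for _ in range(100):
        base = rng.choice(sorted(terms))
        i = rng.randrange(1, len(base))
        cand = base[:i] + rng.choice("xyz") + base[i:]
        costs = []
        for budget in (0, 1, 2, 3):
            cfg = CorrectionConfig(True, budget, 4)
            r = correct_against(a, cand, MODEL, cfg)
            costs.append(None if r in (None, NOT_APPLICABLE) else r.total_cost)
        seen = [c for c in costs if c is not None]
        assert seen == sorted(seen, reverse=True)
        for small, large in zip(costs, costs[1:]):
            if small is not None:
                assert large is not None and large <= small


def test_cost_model_validation():
    with pytest.raises(ValueError):
        EditCostModel(insertion=0)
    with pytest.raises(ValueError):
        EditCostModel(parameterized=(("a", "b", 2.0),))
    with pytest.raises(ValueError):
        CorrectionConfig(max_unparameterized_edits=-1)
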