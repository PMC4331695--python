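"""Demonstrative resources and seeded synthetic corpora.

Everything the test-suite and the worked examples need is generated
here: a small set of nomenclature grammars (alkanes, compound-database
identifiers, CAS registry numbers, sum formulae, vendor registry
codes), toy dictionaries seeded with real example terms (drug names,
allotropes, alloys, common abbreviations, generic chemical classes), the
shipped word lists, and a reproducible corpus generator that assembles
documents from a filler-word pool with entities injected from the
resources' own languages — so gold annotations are exact by
construction and the whole pipeline can be scored with no external
corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .abbrev import AbbrevConfig, EquivalenceMap, corresponds, is_valid_short_form
from .correction import CorrectionConfig
from .curation import RawSynonym
from .engine import Resource, ResourceSet
from .evaluation import GoldAnnotation
from .grammar import CharAutomaton, compile_grammar, parse_grammar
from .lexicon import Lexicon
from .normalize import SourceDocument
from .postprocess import WordLists
from .wordlists import COMMON_ENGLISH_WORDS, STOP_TERMS

__all__ = ["FixtureSpec", "builtin_resources", "builtin_wordlists",
           "generate_corpus", "raw_synonym_fixture",
           "ALKANE_GRAMMAR", "CID_GRAMMAR", "CAS_GRAMMAR",
           "SUM_FORMULA_GRAMMAR", "REGISTRY_GRAMMAR"]

# ---------------------------------------------------------------------------
# grammars

ALKANE_GRAMMAR = """
# straight-chain alkane names
alkaneStem : 'meth' | 'eth' | 'prop' | 'but' | 'pent' | 'hex' | 'hept' | 'oct' | 'non' | 'dec'
alkane : alkaneStem 'ane'
"""

CID_GRAMMAR = """
# compound-database identifier, e.g. CID:2244 (digits 1-9 then any digits)
Digit1to9 : '1' | '2' | '3' | '4' | '5' | '6' | '7' | '8' | '9'
Digit : Digit1to9 | '0'
Cid : 'CID:' Digit1to9 Digit*
"""

CAS_GRAMMAR = """
# CAS registry number: 2-7 digits, hyphen, 2 digits, hyphen, 1 check digit
Digit : '0' | '1' | '2' | '3' | '4' | '5' | '6' | '7' | '8' | '9'
Cas : Digit Digit Digit? Digit? Digit? Digit? Digit? '-' Digit Digit '-' Digit
"""

SUM_FORMULA_GRAMMAR = """
# elemental composition formulae, e.g. C20H25NO6
Digit1to9 : '1' | '2' | '3' | '4' | '5' | '6' | '7' | '8' | '9'
Digit : Digit1to9 | '0'
Element : 'Cl' | 'Ca' | 'Cu' | 'Br' | 'Na' | 'Mg' | 'Fe' | 'Zn' | 'Mn' | 'Al' | 'Si' | 'C' | 'H' | 'N' | 'O' | 'S' | 'P' | 'F' | 'I' | 'K' | 'B'
Count : Digit1to9 Digit*
Part : Element Count?
Formula : Part Part*
"""

REGISTRY_GRAMMAR = """
# vendor registry codes, e.g. GSK2248761: 2-4 capitals then 4-8 digits
Digit1to9 : '1' | '2' | '3' | '4' | '5' | '6' | '7' | '8' | '9'
Digit : Digit1to9 | '0'
Upper : 'A' | 'B' | 'C' | 'D' | 'E' | 'F' | 'G' | 'H' | 'I' | 'J' | 'K' | 'L' | 'M' | 'N' | 'O' | 'P' | 'Q' | 'R' | 'S' | 'T' | 'U' | 'V' | 'W' | 'X' | 'Y' | 'Z'
RegNum : Upper Upper Upper? Upper? Digit1to9 Digit Digit Digit Digit? Digit? Digit? Digit?
"""

# ---------------------------------------------------------------------------
# toy dictionaries (seeded from published example terms)

DRUG_TERMS = {
    "vancomycin", "aspirin", "paracetamol", "ibuprofen", "nornicotine",
    "genistein", "daidzein", "quercetin", "morphine", "nicotine", "caffeine",
    "penicillin", "warfarin", "metformin", "tamoxifen", "cisplatin",
}

TRIVIAL_TERMS = {
    "adam's catalyst", "resorcinol", "formaldehyde", "glutathione",
    "leucine", "proline", "tetrahydrofuran", "methylmercury", "limonene",
    "cholesterol", "glucose", "pyridine", "toluene", "acetone", "urea",
    "cyclic guanosine monophosphate", "chikusetsusaponin L10",
}

ELEMENT_TERMS = {
    "protactinium", "phosphorus", "mercury", "gold", "silver", "sodium",
    "potassium", "titanium", "tungsten",
}

ALLOTROPE_TERMS = {"red phosphorus", "white phosphorus", "graphite",
                   "diamond", "ozone"}

ALLOY_TERMS = {"pig iron", "brass", "bronze", "solder", "amalgam"}

ABBREVIATION_TERMS = {"TMEDA", "DMSO", "DMF", "EDTA", "cGMP", "NADH"}

CHEMICAL_CLASS_TERMS = {
    "alkaloid", "alkaloids", "isoflavonoid", "isoflavonoids", "flavonoid",
    "flavonoids", "monoterpene", "monoterpenes", "sterol", "sterols",
    "glycopeptide", "monosaccharide", "quaternary amine", "keto steroids",
}

POLYMER_TERMS = {"polyethylene glycol 8000", "polystyrene", "polyethylene",
                 "cellulose", "polypropylene"}

#: biochemical polymers blocked from annotation (a blocking dictionary)
NATURAL_POLYMER_TERMS = {"cellulose", "starch", "chitin", "keratin"}


def builtin_resources() -> ResourceSet:
    """The shipped demonstrative resource set: five grammars, seven
    matching dictionaries and one blocking dictionary, with spelling
    correction enabled on the name-like resources."""
    correct = CorrectionConfig(enabled=True, max_unparameterized_edits=1,
                               min_entity_length=4)
    grammars = [
        ("cas_number", CAS_GRAMMAR, "cas_number", correct, False),
        ("cid", CID_GRAMMAR, "cid", correct, False),
        ("registry_number", REGISTRY_GRAMMAR, "registry_number", None, False),
        ("chemical_formula", SUM_FORMULA_GRAMMAR, "formula", None, True),
        ("alkane", ALKANE_GRAMMAR, "chemical", None, False),
    ]
    resources: list[Resource] = []
    for name, source, cls, corr, is_sum in grammars:
        automaton = compile_grammar(parse_grammar(source))
        resources.append(Resource(name=name, matcher=automaton,
                                  entity_class=cls, correction=corr,
                                  is_sum_formula=is_sum))
    lexicons = [
        ("drug", DRUG_TERMS, "drug", correct),
        ("trivial", TRIVIAL_TERMS, "chemical", correct),
        ("element", ELEMENT_TERMS, "element", None),
        ("allotrope", ALLOTROPE_TERMS, "allotrope", None),
        ("alloy", ALLOY_TERMS, "alloy", None),
        ("common_abbreviation", ABBREVIATION_TERMS, "abbreviation", None),
        ("chemical_class", CHEMICAL_CLASS_TERMS, "chemical_class", None),
        ("polymer", POLYMER_TERMS, "polymer", None),
    ]
    for name, terms, cls, corr in lexicons:
        case = "sensitive" if name == "common_abbreviation" else "first-insensitive"
        lex = Lexicon(name=name, terms=set(terms), entity_class=cls,
                      case_policy=case)
        resources.append(Resource(name=name, matcher=lex, entity_class=cls,
                                  correction=corr))
    blocker = Lexicon(name="natural_polymer", terms=set(NATURAL_POLYMER_TERMS),
                      entity_class="polymer", role="blocking",
                      case_policy="first-insensitive")
    resources.append(Resource(name="natural_polymer", matcher=blocker,
                              role="blocking", entity_class="polymer"))
    return ResourceSet(resources=resources)


def builtin_wordlists() -> WordLists:
    return WordLists()


def builtin_equivalence_map() -> EquivalenceMap:
    return EquivalenceMap()


# ---------------------------------------------------------------------------
# the raw-synonym curation fixture (25 terms exercising every filter)

def raw_synonym_fixture() -> list[RawSynonym]:
    return [
        RawSynonym("paracetamol (INN)"),
        RawSynonym("command"),
        RawSynonym("abc"),
        RawSynonym("chloride)"),
        RawSynonym("AstraZeneca"),
        RawSynonym("what?ever"),
        RawSynonym("Ala-Gly hexadecapeptide", peptide_length=16),
        RawSynonym("lacto-N-tetraose", saccharide_length=4),
        RawSynonym("-phenyl"),
        RawSynonym("2,4-D, sodium salt"),
        RawSynonym("KF 17837"),
        RawSynonym("Bisphenol A"),
        RawSynonym("alpha-tocopherol"),
        RawSynonym("vancomycin"),
        RawSynonym("aspirin derivative"),
        RawSynonym("insulin gene"),
        RawSynonym("BMS-123456 (TN)"),
        RawSynonym("BQJCRHHNABKAKU-KBQPJGBKSA-N"),
        RawSynonym("1abc"),
        RawSynonym("sc-560"),
        RawSynonym("XQ-4521", is_depositor_external_name=True),
        RawSynonym("solution"),
        RawSynonym("morphine (XYZ)"),
        RawSynonym("free acid"),
        RawSynonym("gamma-aminobutyric acid"),
    ]


# ---------------------------------------------------------------------------
# corpus generation

@dataclass
class FixtureSpec:
    """Knobs of the synthetic corpus.

    ``entity_density`` is entities per 100 tokens; ``typo_rate`` the
    proportion of (correctable) entities perturbed by one substitution;
    ``abbrev_rate`` the proportion of entities given a parenthetical
    definition; ``pattern_mix`` weights over the six definition forms.
    """

    seed: int = 0
    n_docs: int = 10
    entity_density: float = 8.0
    typo_rate: float = 0.0
    abbrev_rate: float = 0.1
    pattern_mix: dict[str, float] = field(default_factory=lambda: {
        "LF (SF)": 1, "SF (LF)": 1, "LF (SF;": 1,
        "LF (SF,": 1, "(LF, SF)": 1, "SF = LF": 1,
    })

    def __post_init__(self):
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        for rate in (self.typo_rate, self.abbrev_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class InjectionRecord:
    """Audit trail of one injected entity."""

    doc_id: str
    section_label: str
    surface: str            # as written in the document (post-perturbation)
    original: str           # sampled term before any typo
    typo: bool
    abbrev_form: str | None


def _sample_automaton(a: CharAutomaton, rng: random.Random,
                      max_len: int = 20) -> str:
    """Random accepted string: a random walk over the DFA graph."""
    for _ in range(200):
        state = a.start
        out: list[str] = []
        while len(out) < max_len:
            stop_ok = state in a.accepting and out
            choices = sorted(a.transitions[state])
            if stop_ok and (not choices or rng.random() < 0.5):
                return "".join(out)
            if not choices:
                break
            ch = rng.choice(choices)
            out.append(ch)
            state = a.transitions[state][ch]
        if state in a.accepting and out:
            return "".join(out)
    raise RuntimeError("could not sample an accepted string")


def _filler_pool(resources: ResourceSet) -> list[str]:
    """English words that are safe fillers: no resource matches inside
    them and no correction-enabled resource can reach them within its
    edit budget, so they can never seed a spurious entity."""
    from .correction import NOT_APPLICABLE, correct_against

    pool = []
    all_resources = resources.resources
    correctable = [r for r in resources.matching()
                   if r.correction and r.correction.enabled]
    for word in sorted(COMMON_ENGLISH_WORDS):
        if len(word) < 3:
            continue
        hit = False
        for res in all_resources:
            for pos in range(len(word)):
                if res.match_longest(word, pos):
                    hit = True
                    break
            if hit:
                break
        if not hit:
            for res in correctable:
                result = correct_against(res.automaton(), word,
                                         resources.cost_model, res.correction)
                if result is not NOT_APPLICABLE and result is not None:
                    hit = True
                    break
        if not hit:
            pool.append(word)
    return pool


def _make_short_form(term: str, rng: random.Random,
                     eq: EquivalenceMap, cfg: AbbrevConfig,
                     used: set[str]) -> str | None:
    """An acronym-like short form that passes validity + correspondence."""
    words = [w for w in term.split() if w]
    initials = "".join(w[0] for w in words).upper()
    candidates = []
    if len(initials) >= 3:
        candidates.append(initials[:4])
    tail = "".join(ch for ch in words[-1][1:] if ch.isalpha()).upper()
    for extra in range(1, min(4, len(tail))):
        candidates.append((initials + tail[:extra])[:5])
    for sf in candidates:
        if len(sf) < cfg.min_length or sf in used:
            continue
        if is_valid_short_form(sf, cfg) and corresponds(sf, term, eq):
            return sf
    return None


def _sampleable_terms(resources: ResourceSet) -> list[tuple[str, str, str]]:
    """(term, resource name, class) triples usable for injection:
    single- or multi-word dictionary terms that are not stop terms."""
    out = []
    for res in resources.matching():
        if res.name in ("drug", "trivial", "allotrope", "alloy"):
            for term in sorted(res.matcher.terms):
                if term.lower() in STOP_TERMS:
                    continue
                out.append((term, res.name, res.entity_class))
    return out


def generate_corpus(spec: FixtureSpec, resources: ResourceSet | None = None,
                    ) -> tuple[list[SourceDocument], list[GoldAnnotation],
                               list[InjectionRecord]]:
    """Assemble documents with entities injected at known offsets.

    Gold spans are recorded at injection time, so on a noise-free spec
    the pipeline must recover them exactly.  Entities are always
    separated by at least one filler word (side-by-side injected
    entities would legitimately merge into one family-name span and the
    gold would no longer be exact).  Typos are single inner-character
    substitutions applied only to single-word entities from
    correction-enabled resources; abbreviation definitions follow the
    six supported surface forms.  Deterministic in ``spec.seed``.
    """
    resources = resources or builtin_resources()
    rng = random.Random(spec.seed)
    eq = builtin_equivalence_map()
    abbrev_cfg = AbbrevConfig()
    fillers = _filler_pool(resources)
    if len(fillers) < 50:
        raise RuntimeError("filler pool unexpectedly small")
    terms = _sampleable_terms(resources)
    grammar_resources = [(r.name, r.entity_class, r.matcher)
                         for r in resources.matching()
                         if r.name in ("cas_number", "cid", "registry_number")]
    correctable = {r.name for r in resources.matching()
                   if r.correction and r.correction.enabled}

    docs: list[SourceDocument] = []
    gold: list[GoldAnnotation] = []
    records: list[InjectionRecord] = []
    forms = list(spec.pattern_mix)
    weights = [spec.pattern_mix[f] for f in forms]

    for d in range(spec.n_docs):
        doc_id = f"SYN{d:05d}"
        sections = []
        used_sfs: set[str] = set()
        for label, n_tokens in (("T", rng.randint(6, 12)),
                                ("A", rng.randint(80, 140))):
            parts: list[str] = []      # text assembled so far
            offset = 0
            token_budget = n_tokens
            last_was_entity = False
            while token_budget > 0:
                make_entity = (not last_was_entity
                               and rng.random() < spec.entity_density / 100)
                if not make_entity:
                    word = rng.choice(fillers)
                    if parts:
                        parts.append(" ")
                        offset += 1
                    parts.append(word)
                    offset += len(word)
                    token_budget -= 1
                    last_was_entity = False
                    continue

                # choose an entity: dictionary term or grammar sample
                if grammar_resources and rng.random() < 0.25:
                    name, cls, automaton = rng.choice(grammar_resources)
                    surface = original = _sample_automaton(automaton, rng)
                else:
                    original, name, cls = rng.choice(terms)
                    surface = original
                typo = False
                if (spec.typo_rate and name in correctable
                        and " " not in original and len(original) >= 5
                        and rng.random() < spec.typo_rate):
                    surface, ok = _perturb(original, rng, resources)
                    typo = ok and surface != original
                    if not typo:
                        surface = original

                abbrev_form = None
                sf = None
                if (spec.abbrev_rate and not typo and " " not in original
                        and original.isalpha() and len(original) >= 6
                        and rng.random() < spec.abbrev_rate):
                    sf = _make_short_form(original, rng, eq, abbrev_cfg, used_sfs)
                    if sf is not None:
                        abbrev_form = rng.choices(forms, weights)[0]
                        used_sfs.add(sf)

                if parts:
                    parts.append(" ")
                    offset += 1

                if abbrev_form is None:
                    start = offset
                    parts.append(surface)
                    offset += len(surface)
                    gold.append(GoldAnnotation(doc_id, label,
                                               (start, start + len(surface)),
                                               surface, cls))
                else:
                    offset, spans = _emit_definition(
                        parts, offset, surface, sf, abbrev_form, rng, fillers)
                    for s, e_, txt in spans:
                        gold.append(GoldAnnotation(doc_id, label, (s, e_),
                                                   txt, cls))
                    # one later standalone mention of the short form
                    filler = rng.choice(fillers)
                    parts.append(" " + filler)
                    offset += 1 + len(filler)
                    parts.append(" " + sf)
                    gold.append(GoldAnnotation(doc_id, label,
                                               (offset + 1, offset + 1 + len(sf)),
                                               sf, cls))
                    offset += 1 + len(sf)
                    token_budget -= 3
                records.append(InjectionRecord(doc_id, label, surface,
                                               original, typo, abbrev_form))
                token_budget -= 1
                last_was_entity = True
            sections.append((label, "".join(parts)))
        docs.append(SourceDocument(doc_id=doc_id, sections=tuple(sections)))
    return docs, gold, records


def _perturb(term: str, rng: random.Random,
             resources: ResourceSet) -> tuple[str, bool]:
    """One inner-character substitution that no resource matches exactly
    afterwards (so that only spelling correction can recover it)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(20):
        i = rng.randrange(1, len(term) - 1)
        repl = rng.choice(letters)
        if repl == term[i]:
            continue
        cand = term[:i] + repl + term[i + 1:]
        clash = any(
            res.match_longest(cand, pos)
            for res in resources.resources for pos in range(len(cand)))
        if not clash:
            return cand, True
    return term, False


def _emit_definition(parts: list[str], offset: int, surface: str, sf: str,
                     form: str, rng: random.Random,
                     fillers: list[str]) -> tuple[int, list[tuple[int, int, str]]]:
    """Append one abbreviation-definition construct; returns the new
    offset and the (start, end, text) gold spans it creates."""
    spans: list[tuple[int, int, str]] = []

    def put(text: str, is_gold: bool = False):
        nonlocal offset
        if is_gold:
            spans.append((offset, offset + len(text), text))
        parts.append(text)
        offset += len(text)

    if form == "LF (SF)":
        put(surface, True)
        put(" (")
        put(sf, True)
        put(")")
    elif form == "SF (LF)":
        put(sf, True)
        put(" (")
        put(surface, True)
        put(")")
    elif form == "LF (SF;":
        put(surface, True)
        put(" (")
        put(sf, True)
        put("; " + rng.choice(fillers) + ")")
    elif form == "LF (SF,":
        put(surface, True)
        put(" (")
        put(sf, True)
        put(", " + rng.choice(fillers) + ")")
    elif form == "(LF, SF)":
        put("(")
        put(surface, True)
        put(", ")
        put(sf, True)
        put(")")
    elif form == "SF = LF":
        put(sf, True)
        put(" = ")
        put(surface, True)
    else:  # pragma: no cover
        raise ValueError(f"unknown abbreviation form {form!r}")
    return offset, spans
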