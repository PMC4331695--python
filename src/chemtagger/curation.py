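"""Filter-and-expand curation of raw synonym dumps.

Public chemical-structure databases carry synonym lists dominated by
database identifiers, supplier catalogue numbers, protein names and
plain English words.  Used raw as a dictionary they destroy precision.
This module turns a raw synonym list into a precise lexicon by running
an ordered series of reject filters and, for surviving terms, a set of
variant-expansion rules (Greek-letter spellings, joined/hyphenated
forms of trailing identifiers).

Every decision is machine-auditable: a rejected term carries the reason
code of the *first* failing filter, so re-ordering the filters is an
observable change.  The filter order is fixed as:

  biopolymer, unbalanced_brackets, unknown_qualifier (after stripping
  known bracketed qualifiers), context_qualifier, too_short,
  hyphen_boundary, comma_space, blocked_by_dictionary, dubious_synonym,
  english_word, dubious_word, depositor_external_name,
  catalogue_number, forbidden_character, pdb_code, inchi_key
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .wordlists import COMMON_ENGLISH_WORDS

__all__ = [
    "RawSynonym",
    "CurationConfig",
    "CurationResult",
    "curate_synonym",
    "expand_variants",
    "curate_file",
    "GREEK_LETTERS",
]

GREEK_LETTERS: dict[str, str] = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "zeta": "ζ", "eta": "η", "theta": "θ", "iota": "ι", "kappa": "κ",
    "lambda": "λ", "mu": "μ", "nu": "ν", "xi": "ξ", "omicron": "ο",
    "pi": "π", "rho": "ρ", "sigma": "σ", "tau": "τ", "upsilon": "υ",
    "phi": "φ", "chi": "χ", "psi": "ψ", "omega": "ω",
}

FORBIDDEN_CHARACTERS = frozenset("?!\\|%@;")

#: qualifiers that may be stripped when trailing in brackets
DEFAULT_KNOWN_QUALIFIERS = frozenset({
    "INN", "USAN", "BAN", "JAN", "USP", "TN", "DCF", "NF", "MART.", "VAN",
})

DEFAULT_CONTEXT_QUALIFIERS = frozenset({
    "derivative", "derivatives", "analog", "analogs", "analogue",
    "analogues", "solution", "solutions",
})

DEFAULT_DUBIOUS_SYNONYMS = frozenset({
    "astrazeneca", "glaxosmithkline", "sigma-aldrich", "novartis", "pfizer",
})

DEFAULT_DUBIOUS_WORDS = frozenset({
    "gene", "genes", "inhibitor", "inhibitors", "protein", "proteins",
    "receptor", "receptors", "antibody", "antibodies",
})

#: supplier-style catalogue number shapes, config-replaceable.  The
#: prefixes are deliberately specific so that research-code names such
#: as "KF-17837" are not caught.
DEFAULT_CATALOGUE_PATTERNS = (
    r"^sc-\d{3,}$",                  # Santa Cruz style
    r"^ab\d{4,}$",                   # Abcam style
    r"^hy-[a-z]?\d{3,}[a-z]?$",      # MedChemExpress style
    r"^(?:cat|item|prod)\.? ?(?:no\.? ?)?[a-z0-9-]+$",
)

_INCHI_KEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
_PDB_CODE_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
_TRAILING_QUALIFIER_RE = re.compile(r"\s*\(([^()]*)\)\s*$")
_QUALIFIER_SHAPE_RE = re.compile(r"^[A-Z][A-Z.]{1,7}$")


@dataclass(frozen=True)
class RawSynonym:
    """One line of a synonym dump.

    ``peptide_length``/``saccharide_length`` are pre-computed from the
    associated structure when available (structure perception itself is
    out of scope); ``is_depositor_external_name`` marks supplier
    catalogue identifiers.
    """

    term: str
    peptide_length: int | None = None
    saccharide_length: int | None = None
    is_depositor_external_name: bool = False

    def __post_init__(self):
        if not self.term:
            raise ValueError("empty synonym term")


@dataclass
class CurationConfig:
    known_qualifiers: frozenset[str] = DEFAULT_KNOWN_QUALIFIERS
    context_qualifiers: frozenset[str] = DEFAULT_CONTEXT_QUALIFIERS
    dubious_synonyms: frozenset[str] = DEFAULT_DUBIOUS_SYNONYMS
    dubious_words: frozenset[str] = DEFAULT_DUBIOUS_WORDS
    english_words: frozenset[str] = frozenset(COMMON_ENGLISH_WORDS)
    catalogue_number_patterns: tuple[str, ...] = DEFAULT_CATALOGUE_PATTERNS
    forbidden_characters: frozenset[str] = FORBIDDEN_CHARACTERS
    #: lexicons whose matches reject a synonym ("matched by another
    #: dictionary"); each needs a __contains__ over full strings
    blocking_lexicons: tuple = ()
    max_peptide_length: int = 15   # hexadecapeptide or longer is a biopolymer
    max_saccharide_length: int = 3  # tetrasaccharide or longer is a biopolymer
    min_length: int = 4             # reject if ≤ 3 characters


@dataclass(frozen=True)
class CurationResult:
    status: str                      # accepted | rejected
    reason: str | None = None        # first failing filter when rejected
    cleaned_term: str | None = None
    variants: frozenset[str] = frozenset()

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _brackets_balanced(term: str) -> bool:
    pairs = {")": "(", "]": "[", "}": "{"}
    stack: list[str] = []
    for ch in term:
        if ch in "([{":
            stack.append(ch)
        elif ch in pairs:
            if not stack or stack[-1] != pairs[ch]:
                return False
            stack.pop()
    return not stack


def _words(term: str) -> list[str]:
    return [w for w in re.split(r"\s+", term) if w]


def curate_synonym(s: RawSynonym, cfg: CurationConfig | None = None) -> CurationResult:
    """Apply the reject filters in their fixed order, then expand
    variants for accepted terms.  Rejection is a result, not an error."""
    cfg = cfg or CurationConfig()
    term = s.term.strip()

    if s.peptide_length is not None and s.peptide_length > cfg.max_peptide_length:
        return CurationResult("rejected", "biopolymer")
    if s.saccharide_length is not None \
            and s.saccharide_length > cfg.max_saccharide_length:
        return CurationResult("rejected", "biopolymer")

    if not _brackets_balanced(term):
        return CurationResult("rejected", "unbalanced_brackets")

    # strip a trailing bracketed qualifier; unknown qualifier-shaped text
    # in that position is a reject
    m = _TRAILING_QUALIFIER_RE.search(term)
    if m:
        inner = m.group(1).strip()
        if inner.upper() in cfg.known_qualifiers:
            term = term[:m.start()].rstrip()
        elif _QUALIFIER_SHAPE_RE.match(inner) and inner.upper() not in cfg.known_qualifiers \
                and not any(c.isdigit() for c in inner):
            return CurationResult("rejected", "unknown_qualifier")

    words = _words(term)
    lowered = [w.lower() for w in words]
    if words and (lowered[0] in cfg.context_qualifiers
                  or lowered[-1] in cfg.context_qualifiers):
        return CurationResult("rejected", "context_qualifier")

    if len(term) < cfg.min_length:
        return CurationResult("rejected", "too_short")

    if term.startswith("-") or term.endswith("-"):
        return CurationResult("rejected", "hyphen_boundary")

    if ", " in term:
        return CurationResult("rejected", "comma_space")

    for lex in cfg.blocking_lexicons:
        if term in lex:
            return CurationResult("rejected", "blocked_by_dictionary")

    if term.lower() in cfg.dubious_synonyms:
        return CurationResult("rejected", "dubious_synonym")

    if words:
        first = lowered[0].strip("-")
        if first in cfg.english_words and not (
                len(lowered) > 1 and lowered[1] == "acid"):
            return CurationResult("rejected", "english_word")

    if any(w.strip("()-,.") in cfg.dubious_words for w in lowered):
        return CurationResult("rejected", "dubious_word")

    if s.is_depositor_external_name:
        return CurationResult("rejected", "depositor_external_name")

    for pattern in cfg.catalogue_number_patterns:
        if re.match(pattern, term, flags=re.IGNORECASE):
            return CurationResult("rejected", "catalogue_number")

    if any(ch in cfg.forbidden_characters for ch in term):
        return CurationResult("rejected", "forbidden_character")

    if _PDB_CODE_RE.match(term):
        return CurationResult("rejected", "pdb_code")

    if _INCHI_KEY_RE.match(term):
        return CurationResult("rejected", "inchi_key")

    return CurationResult("accepted", None, term, frozenset(expand_variants(term)))


def expand_variants(term: str) -> set[str]:
    """Variant spellings of an accepted term.

    * Greek letters written out in Latin (``alpha-``, or as a standalone
      word) additionally generate the Greek-character spelling.
    * If the last word is all digits, forms with the preceding space
      deleted and replaced by a hyphen are added.
    * If the last word is a letter, or a letter followed by a digit, a
      hyphenated form is added.

    The original term is always in the returned set.
    """
    variants = {term}

    # Greek-letter spellings (attached "alpha-" and standalone "alpha")
    for latin, greek in GREEK_LETTERS.items():
        pattern = re.compile(
            rf"(?i)(?<![a-z])({latin})(?=-)|(?<![a-z])({latin})(?![a-z])")
        for v in list(variants):
            if pattern.search(v):
                variants.add(pattern.sub(greek, v))

    out = set(variants)
    for v in variants:
        words = v.rsplit(" ", 1)
        if len(words) != 2:
            continue
        head, last = words
        if last.isdigit():
            out.add(f"{head}-{last}")
            out.add(f"{head}{last}")
        elif re.fullmatch(r"[A-Za-z]\d?", last):
            out.add(f"{head}-{last}")
    return out


def curate_file(rows, cfg: CurationConfig | None = None):
    """Curate an iterable of :class:`RawSynonym`; yields
    ``(synonym, result)`` pairs in input order."""
    cfg = cfg or CurationConfig()
    for syn in rows:
        yield syn, curate_synonym(syn, cfg)


def read_raw_synonyms(path: str | Path):
    """Read a raw-synonym TSV: term, optional peptide_length,
    saccharide_length and depositor flag columns."""
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        term = parts[0]
        pep = int(parts[1]) if len(parts) > 1 and parts[1] else None
        sac = int(parts[2]) if len(parts) > 2 and parts[2] else None
        dep = len(parts) > 3 and parts[3].strip().lower() in ("1", "true", "yes")
        rows.append(RawSynonym(term, pep, sac, dep))
    return rows
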