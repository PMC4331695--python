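"""Shipped word lists.

These are deliberately small, documented defaults: a common-English
vocabulary used by the curation filters and as entity-extension
boundaries, noise words, boundary-trim terms, stop terms that the
annotation guidelines exclude, a specific-is-a-generic relation table
and the long↔short token equivalences used by abbreviation matching.
Each is config-replaceable; the shipped content is what the test
fixtures exercise.
"""

from __future__ import annotations

# A compact common-English word list (lower-case).  Not a linguistic
# resource: it is the vocabulary the curation english-word filter and
# the entity-extension boundary test consult, and it doubles as the
# filler pool for synthetic corpora.
COMMON_ENGLISH_WORDS: frozenset[str] = frozenset("""
a about above across after again against all almost alone along already
also although always among amount an analysis and animal announce another
answer any appear approach area argue around arrive article ask assume at
available average away back based be became because become been before
begin behind being believe below between big board body book both bring
but by call came can cannot care carry case cause certain change chapter
clear close come command common company compare complete concern condition
consider contain continue control could country course cover culture cut
data day decide decrease define degree describe design detail determine
develop difference different difficult direct discuss distance do doctor
does done down draw drive due during each early easy effect effort eight
either end enough entire error estimate even event ever every evidence
exactly example experiment explain express fact factor fall family far
feel few field figure final find fine first five focus follow for force
form found four free from full further future general get give go good
great ground group grow had half hand happen hard has have he head hear
help her here high him his history hold home hour house how however human
idea if important improve in include increase indeed indicate individual
information instead interest into involve is issue it its itself just
keep kind know known large last late later lead learn least leave left
less let letter level lie life light like likely limit line list little
local long look low machine made main major make manner many material may
mean measure meet member method middle might model moment more most move
much must my near nearly need never new next night nine no none nor not
note nothing now number observe obtain occur of off offen often old on
once one only open opinion optimizer or order other our out over own page
paper part particular pass past pattern people per perhaps period person
picture place plan play point policy position possible power practice
present press pressure probably problem procedure process procure produce
product program provide public purpose put question quite raise range
rate rather reach read real really reason receive recent record red
reduce refer regard relate remain remember remove report represent
require research respect rest result return right rise role room rule
run said same sample say school science second section see seem seen
sense series serve set seven several shall she short should show side
significant similar simple simply since single situation six size small
so social some something sometimes soon sound source speak special
specific stand standard start state statement station stay step still
stop strong structure study subject such suggest support suppose sure
surface surpass system table take talk tell ten term test text than that
the their them themselves then theory there therefore these they thing
think third this those though three through thus time to today together
too total toward training treatment true try turn two type under
understand unit until up upon us use usually value various very view
voice walk want was watch way we week well went were what when where
whether which while white who whole whose why wide will with within
without word work world would write written year yet you young your
""".split())

#: corpus-specific noise words that block entity extension but are not
#: ordinary English (section labels, units written out, etc.)
NOISE_WORDS: frozenset[str] = frozenset({
    "via", "versus", "vs", "et", "al", "ie", "eg", "fig", "figs",
    "mg", "ml", "kg", "nm", "mm", "min", "h", "wt",
    "transferase", "transferases", "synthase", "kinase", "oxidase",
})

#: non-essential boundary modifiers trimmed off entity edges
TRIM_TERMS: frozenset[str] = frozenset({
    "group", "groups", "colloidal", "dye", "dyes", "nanoparticles",
    "nanoparticle", "particles", "particle", "moiety", "moieties",
    "residue", "residues", "atom", "atoms", "salt", "salts",
})

#: terms excluded outright when an entity reduces to them after trimming
STOP_TERMS: frozenset[str] = frozenset({
    "gold", "water", "lead", "iron",
})

#: (specific, generic) pairs: the specific term IS an instance of the
#: generic class, so "specific generic" side-by-side is two mentions,
#: not one merged family name.  Format matches a two-column TSV export
#: of an ontology's is-a closure.
INSTANCE_OF: frozenset[tuple[str, str]] = frozenset({
    ("genistein", "isoflavonoid"),
    ("genistein", "flavonoid"),
    ("daidzein", "isoflavonoid"),
    ("quercetin", "flavonoid"),
    ("nicotine", "alkaloid"),
    ("morphine", "alkaloid"),
    ("cholesterol", "sterol"),
    ("limonene", "monoterpene"),
    ("vancomycin", "glycopeptide"),
    ("glucose", "monosaccharide"),
})

#: long-form token → short-form token equivalences for abbreviation
#: matching (element symbols, common organic shorthand)
EQUIVALENCE_MAP: dict[str, str] = {
    "mercury": "Hg",
    "methyl": "Me",
    "ethyl": "Et",
    "propyl": "Pr",
    "butyl": "Bu",
    "phenyl": "Ph",
    "acetyl": "Ac",
    "benzyl": "Bn",
    "sodium": "Na",
    "potassium": "K",
    "iron": "Fe",
    "copper": "Cu",
    "zinc": "Zn",
    "silver": "Ag",
    "tin": "Sn",
    "lead": "Pb",
}
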