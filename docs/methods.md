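# Methods

This note records the models, parameters and design choices behind
`chemtagger`, in the order the pipeline runs them, together with what
the synthetic-data generator does and does not emulate.

## Normalization

Many Unicode characters are interchangeable for a chemical-name
matcher.  The default table folds backtick, curly single quotes and
prime to the apostrophe, curly double quotes to `"`, en/em dash and the
minus sign to `-`, expands `œ/Œ/æ/Æ` to two-letter sequences, and maps
the no-break space to a space.  The table is deliberately a small,
config-extensible superset of the obvious cases rather than an attempt
at exhaustive Unicode coverage.  Greek letters are *not* folded to
Latin; instead the curation module generates Greek-character variants
of Latin-spelled terms, which keeps dictionary text and document text
on the same side of the mapping.

Offsets are 0-based, half-open, counted in code points of the original
text.  Each normalized character stores the half-open source range that
produced it (a one-to-two expansion such as `œ`→`oe` gives both output
characters the same one-character source range); `map_span` returns the
minimal covering source range of a normalized span.  In XML mode the
stylistic tags `sub`, `sup`, `i`, `b` are dropped and every other tag
becomes a single newline mapped to an empty source range; tag nesting
is checked with a stack and malformed markup raises an error carrying
the source offset.  `lxml` is installed but does not expose character
offsets of text nodes, which the index map requires, so tags are
scanned with an offset-tracking tokenizer and validated structurally.

## Grammars and automata

The grammar dialect is one rule per line (`name : production`),
alternation `|`, juxtaposition for concatenation, postfix `*` and `?`,
parenthesised groups, single-quoted literals, `$name` dictionary
references and `#` comments.  Regularity is enforced by requiring the
rule-reference graph to be acyclic — a rule may not reference itself
directly or transitively — which makes full inlining terminate and
keeps every grammar regular by construction.  Compilation is Thompson
NFA construction followed by subset construction; machines are not
minimized (language equality, pinned by the oracle tests, is the
contract, not state count).  Transition labels are single characters;
case-insensitive resources are handled by alphabet folding at build
time rather than at match time.

Bracket nesting is not expressible in a regular language, so matching
maintains a stack of `( ) [ ] { }`: a prefix is only reported when the
machine is in an accepting state *and* the brackets seen are balanced
and well nested.  An ill-nested close poisons all longer prefixes.

The layered (two-level) machine compiles a master grammar over an
alphabet of sub-machine names.  Matching is dynamic programming over
(text position, master state); every accepted prefix of an outgoing
sub-machine advances the master one labelled transition.  Sub-machines
may not match empty strings, which guarantees progress, and bracket
validity is judged globally over the whole candidate span rather than
per sub-match, since a bracket may open in one sub-match and close in a
later one.

## Lexicons

Term lists compile to character tries.  Case policies: `sensitive`,
`insensitive`, `first-insensitive` (the default for chemical-name
dictionaries — a sentence-initial capital must not break a match while
interior acronym casing is preserved), and `per-term` (each term flags
its own sensitivity, as curated drug/chemical resources commonly do).
Token-boundary enforcement is per-resource and off for chemical
dictionaries: sub-word matches must remain possible because entity
extension builds on them; it is on for English-word resources, where a
match inside another word is meaningless.

## Curation

Filters run in a fixed order (the order determines the reason code a
rejected term carries): structure-derived biopolymer test
(peptides ≥ 16 residues, saccharides ≥ 4 units, consuming pre-computed
lengths — structure perception is out of scope), unbalanced brackets,
trailing bracketed qualifier handling (known qualifiers such as
`(INN)`/`(TN)` are stripped; an unknown all-caps qualifier-shaped
trailer rejects), leading/trailing context qualifiers ("derivative",
"analog", "solution"), length ≤ 3, hyphen at either end, comma+space,
membership in another configured dictionary, known dubious synonyms,
non-chemical English first word (exempt when the second word is
"acid"), dubious words ("gene", "inhibitor"), depositor catalogue
flags, catalogue-number regexes (supplier-specific prefixes, chosen
narrow enough that research codes like `KF-17837` survive), the
forbidden characters `? ! \ | % @ ;`, PDB-code shape (digit + 3
alphanumerics) and InChI-key shape (14-10-1 uppercase blocks).

Accepted terms expand: written-out Greek letters (attached `alpha-` or
standalone) generate Greek-character variants; a trailing digit word
generates joined and hyphenated forms; a trailing single letter or
letter+digit generates a hyphenated form.  Expansion output is
re-checked against all filters in tests.

The shipped English word list (~800 common words) is a documented
stand-in for a proper vocabulary; it doubles as the corpus generator's
filler pool.

## Spelling correction

Correction searches for the cheapest edit sequence carrying a candidate
token into the language of a resource's automaton.  Generic insertion,
deletion, substitution and adjacent transposition each cost 1.0 and are
limited by a per-resource budget; parameterized known-error rewrites
cost 0.3 and are unlimited (`rn`↔`m`, `l`↔`1`, `O`↔`0`,
`floro`→`fluoro`, space deletion, `,`→`.`, hyphen insertion).  The
numeric costs are fixed, documented defaults pinned by tests, not
empirically fitted.  Setting the generic budget to zero restricts a
resource to known error classes only — the right setting for clean
text, where generic edits mostly manufacture false positives.

The algorithm is uniform-cost search over (automaton state, candidate
position, generic edits used); with positive edge costs the first goal
settled is cost-minimal.  Ties break by fewest edits, then earliest
edit positions, then lexicographically smallest corrected string, which
makes results deterministic.  A candidate shorter than
`min_entity_length` (default 4) or a disabled config short-circuits to
a distinct "not applicable" result.  Optimality is tested against an
independent dynamic-programming minimizer over explicit term lists.

## Annotation engine

Every position of the normalized text is a candidate start for every
matching resource (longest bracket-valid match per resource).
Sum-formula candidates are emitted only when the matched text contains
more than two digits; one- and two-digit "formulae" are dominated by
gene/cell-line names (`CDK2`, `HeLa`) and lone element symbols, so the
digit restriction lives at the grammar-match level where it also keeps
downstream stages (extension, abbreviation propagation) from building
on doomed matches.  Spelling correction then runs over whitespace
tokens not covered by any exact candidate, trying each
correction-enabled resource and keeping the cheapest result.  Matches
inside any blocking-dictionary span are suppressed.  Overlaps resolve
longest-span-first with manifest order breaking ties — an auditable,
deterministic choice.  Include and stop lists are ordinary lexicons;
the stop list defaults to off because suppressing partial-entity
strings costs more recall than the precision it buys, while include
lists are derived greedily: a candidate term is retained only if adding
it strictly increases corpus F1.

## Entity modification

The five steps run in fixed order, per section.

1. **Extension** grows a span left and right until whitespace, a
   bracket that cannot be matched within the span, a word on the
   boundary vocabulary (English words, noise words, and trim terms —
   including trim terms keeps the whole pipeline idempotent), or
   sentence punctuation (`.,;:` adjacent to whitespace or a closing
   bracket; a comma inside `2,4-D` is not a boundary).  An entity
   entirely enclosed in balanced brackets retries extension from
   outside the brackets, adopting the outer boundaries only if they
   grow past the bracket pair itself.  Two entities of
   concrete-structure classes joined by a hyphen are left unfused (that
   shape typically denotes a mixture, e.g. `Resorcinol-Formaldehyde`);
   "concrete-structure" is operationalized as a class set
   (drug/chemical/formula/identifier classes, not generic family or
   polymer classes).
2. **Trimming** strips boundary trim terms with their connecting
   whitespace/hyphens; an entity trimmed to nothing is removed.
3. **Merging** joins overlapping entities unconditionally and
   single-space-adjacent entities unless the pair (either direction) is
   in the instance-of table (`genistein` IS an `isoflavonoid`, so the
   two stay separate).  The merged record keeps a composite
   class/resource string and the `merged` flag, so attribution
   survives.  The shipped instance-of table is a small fixture in the
   two-column TSV shape an ontology is-a export would produce.
4. **Stop-term removal** re-trims and drops entities whose remaining
   text is exactly a stop term (`gold nanoparticles` → trim
   `nanoparticles` → stop `gold`); partial matches (`gold chloride`)
   are unaffected.
5. The **S-transferase case**: within
   `glutathione[- ]S-transferase`, the pattern table extends the
   glutathione entity over the `S`.

Running the full pipeline twice equals running it once on all fixtures;
this is a regression-tested property, and it is why extension refuses
to absorb trim terms that step 2 would immediately remove.

## Abbreviations

Detection recognizes six definition shapes (`LF (SF)`, `SF (LF)`,
`LF (SF;`, `LF (SF,`, `(LF, SF)`, `SF = LF`) with a depth-tracking
bracket scan, so short forms may themselves contain balanced brackets.
Long forms must be entities already found — which removes the classic
uncertainty about where a long form starts.  A short form must be at
least 3 characters (configurable), bracket-balanced, not a Roman
numeral (`II`), and not a compound identifier (digit+letters or
letter+digit, ≤ 3 characters, e.g. `1a`).  The pairing test requires
every alphanumeric of the short form to appear in order in the long
form with the first character word-initial; the long form is first
rewritten with a longest-token-first equivalence map so `MeHg` pairs
with `methylmercury`.  Accepted short forms are propagated to every
non-embedded, non-overlapping occurrence of the exact string
(case-sensitive) in the document, inheriting the long form's class and
resource with a `propagated` flag.

Removal runs the same machinery in reverse: an entity sitting in a
defining pattern whose discovered long form (right-to-left
Schwartz–Hearst scan bounded to min(|SF|+5, 2·|SF|) words, anchored at
a word-initial first character, searched within the enclosing paragraph
segment) neither is nor overlaps an entity is deemed a false positive
and removed with all other instances of its text.  An entity that is
itself the long form of a `(LF, SF)` definition is exempted — without
that guard the rule can consume its own definitions.

## Evaluation

Micro-averaged: TP/FP/FN are pooled over all documents and sections
before precision, recall and F1 are formed; a prediction is a TP iff a
gold annotation has the identical (document, section, start, end);
duplicate identical predictions count once with a warning; class labels
ride along in the files but are ignored for matching.  Gold files are
`doc_id, T|A, start, end, text, class` TSV; prediction files are
`doc_id, SECTION:start:end, rank, confidence` with rank positional and
confidence constant (the system does not score matches).

## Synthetic corpora

The generator assembles title/abstract documents from a filler pool and
injects entities from the shipped resources' own languages (dictionary
terms, plus random accepted walks over the identifier grammars, capped
at 20 characters for readability), recording gold spans at injection
time.  Defaults: 10 documents, ~8 entities per 100 tokens, no typos,
10 % of eligible entities given a parenthetical definition with a
uniform mix over the six surface forms; the recovery experiments use
100 documents, a 15 % abbreviation rate, and 20 % single-substitution
typos — sizes chosen so the full run completes in seconds while still
exercising every stage several hundred times.  Typos are single
inner-character substitutions applied only to single-word entities of
correction-enabled resources, constrained so that no resource matches
the perturbed form exactly (only correction can recover it), and every
perturbation is recorded in an audit trail.  The filler pool is
validated at generation time: a filler may neither contain a resource
match nor be reachable by any correction-enabled resource within its
edit budget.  Entities are always separated by at least one filler
word, because space-adjacent injected entities would legitimately merge
into a family-name span and the recorded gold would no longer be the
pipeline's correct answer.

What passing these corpora shows — and does not.  Exact recovery
(P = R = 1 on clean corpora, recall returning to the clean value under
20 % typos) demonstrates that every stage composes correctly and that
correction is sound and sufficient for its designed error class.  The
corpora do not emulate real biomedical prose: no morphological
ambiguity between chemical and ordinary words, no novel nomenclature
outside the shipped grammars, no OCR noise, no nested definitions.
Scores on them say nothing about performance on real abstracts, which
depends overwhelmingly on dictionary and grammar coverage that a
desk-scale resource set deliberately does not have.

## Numerical and degenerate-input choices

Empty documents yield empty entity lists; an empty lexicon is a
construction error; a grammar whose reference graph has a cycle fails
at parse time with the cycle named.  Costs and comparisons in the
correction search use exact float arithmetic on sums of 0.3/1.0 with a
deterministic total order on the priority queue, so results are
reproducible across runs.  The correction search carries a 500 000-node
safety valve that returns "no correction" rather than stalling on a
pathological automaton; the shipped resources stay orders of magnitude
below it.

## Known limitations

Systematic-nomenclature coverage is a demonstrative subset (alkanes,
identifiers, formulae), not a full IUPAC grammar; the dictionaries are
toy-scale; per-term case folding approximates rather than reproduces
curated-resource conventions when converting a per-term lexicon to a
correction automaton; the English word list is small; and the
extension boundary set (whitespace, mismatched bracket, boundary word,
sentence punctuation) is a documented operationalization of rules that
admit edge cases — `/`- or `→`-joined constructs, for instance, are
extended over rather than split.
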