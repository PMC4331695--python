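# chemtagger

Grammar- and dictionary-driven chemical named-entity recognition.

Chemical mentions in scientific text split into two populations:
**systematic names** ("ethylbenzene", "2634-33-5", "C20H25NO6") that are
generated by nomenclature rules and can be recognized by a formal
grammar, and **trivial names** ("aspirin", "vancomycin") that can only
be recognized by dictionary lookup.  `chemtagger` implements the
rule-driven alternative to machine-learning taggers: every entity it
emits is attributable to exactly one named grammar or dictionary, so a
false positive can be pinpointed to the resource that produced it and a
false negative fixed by adding one rule or term.  The package is aimed
at text-mining practitioners in cheminformatics and drug discovery who
need auditable, correctable annotation rather than a black-box model.

## What it does

* **Normalization** — quote-like, dash-like and ligature characters are
  folded to a canonical alphabet; a bidirectional index map reports all
  entity spans in original source coordinates.  Simple XML is handled by
  dropping stylistic tags (`H<sub>2</sub>O` → `H2O`) and treating other
  tags as paragraph breaks.
* **Grammars → finite-state machines** — rules such as

  ```
  alkaneStem : 'meth' | 'eth' | 'prop'
  alkane     : alkaneStem 'ane'
  ```

  are verified regular (the rule-reference graph must be acyclic),
  inlined, and compiled by Thompson construction + subset construction
  into a DFA.  A two-level machine — a master automaton whose transition
  labels are themselves automata — keeps global nomenclature context
  separate from local token matching.  Because bracket nesting is not
  regular, matching carries a bracket stack: a span is only reported
  when its `()[]{}` are balanced and well nested.
* **Lexicons** — named term lists compiled to tries with per-dictionary
  case policy (including per-term sensitivity) and a *matching* or
  *blocking* role; blocking dictionaries only suppress other matches.
* **Curation** — an ordered filter-and-expand pipeline turns a raw
  synonym dump into a precise lexicon, with a machine-readable reason
  code for every rejection and variant expansion (Greek-letter
  spellings, `KF 17837` → `KF-17837`/`KF17837`) for every acceptance.
* **Spelling correction** — uniform-cost search over
  (automaton state × candidate position) finds the minimum-cost edit
  sequence turning a near-miss token into an accepted string.  Known
  error classes (OCR confusions, `floro`→`fluoro`, erroneous space,
  comma-for-period, missing hyphen) have reduced parameterized costs and
  do not count against the per-resource generic-edit budget.
* **Entity modification** — five ordered steps refine boundaries:
  extension to whitespace/mismatched-bracket/English-word boundaries
  (`nornicotine` → `(S)-nornicotine`), trimming of non-essential
  modifiers (`colloidal silver` → `silver`), merging of
  overlapping/adjacent entities into family names (`monoterpene pyridine
  alkaloids`) unless one is a known instance of the other (`genistein
  isoflavonoid` stays two mentions), stop-term removal (`gold
  nanoparticles` → nothing), and the glutathione-S-transferase special
  case.
* **Abbreviations** — a Schwartz–Hearst-style detector over six surface
  forms (`LF (SF)`, `SF (LF)`, `LF (SF;`, `LF (SF,`, `(LF, SF)`,
  `SF = LF`) pairs short forms with already-found entities, using a
  token equivalence map (mercury→Hg, so `MeHg` ↔ `methylmercury`), and
  propagates accepted short forms document-wide.  The same machinery in
  reverse removes entities that are abbreviations of non-chemical long
  forms (`current good manufacturing practice (cGMP)`).
* **Evaluation** — mention-level micro-averaged precision/recall/F1 on
  exact spans, TSV readers/writers for gold and prediction files, and
  greedy include-list derivation that keeps a candidate term only if it
  strictly increases corpus F1.

Shipped resources are a demonstrative desk-scale set: alkane, compound
identifier (`CID:…`), CAS-number, sum-formula and vendor registry-code
grammars plus toy drug/trivial/element/allotrope/alloy/abbreviation/
class/polymer dictionaries, with a seeded synthetic-corpus generator so
the whole system is testable without downloading any corpus.

## Worked example

```python
from chemtagger import SourceDocument, PipelineConfig, run_pipeline
from chemtagger.fixtures import builtin_resources

doc = SourceDocument("PMID001", (
    ("T", "Spelling correction of asp1rin and (S)-nornicotine boundaries"),
    ("A", "Tetrahydrofuran (THF) was dried over 2634-33-5. "
          "Later THF and monoterpene pyridine alkaloids were assayed; "
          "CDK2 and C20H25NO6 were controls."),
))
entities, report = run_pipeline([doc], builtin_resources(), PipelineConfig())
for e in entities:
    print(f"{e.section_label} {e.span[0]:>3}-{e.span[1]:<3} {e.text!r:35} "
          f"class={e.entity_class:<10} resource={e.resource_name:<16} "
          f"flags={','.join(sorted(e.provenance_flags)) or '-'}")
```

prints

```
A   0-15  'Tetrahydrofuran'                   class=chemical   resource=trivial          flags=-
A  17-20  'THF'                               class=chemical   resource=trivial          flags=abbreviation
A  37-46  '2634-33-5'                         class=cas_number resource=cas_number       flags=-
A  54-57  'THF'                               class=chemical   resource=trivial          flags=propagated
A  62-92  'monoterpene pyridine alkaloids'    class=chemical_class+chemical+chemical_class resource=chemical_class+trivial+chemical_class flags=merged
A 116-125 'C20H25NO6'                         class=formula    resource=chemical_formula flags=-
T  23-30  'asp1rin'                           class=drug       resource=drug             flags=-
T  35-50  '(S)-nornicotine'                   class=drug       resource=drug             flags=extended
```

Reading the output: the abbreviation `THF` was defined once and
propagated to its later occurrence with the long form's class and
resource; the typo `asp1rin` was recovered by a parameterized `1`→`l`
correction against the drug dictionary and is reported at its source
span; three adjacent entities merged into the family name `monoterpene
pyridine alkaloids` with composite attribution; `CDK2` was *not*
annotated because a sum formula must contain more than two digits;
`(S)-nornicotine` shows entity extension beyond the dictionary match
`nornicotine`.

The same pipeline is scriptable from the shell:

```
chemtagger gen-fixtures --seed 3 --n-docs 20 --out corpus/
chemtagger annotate --manifest corpus/manifest.yaml --in corpus/documents.txt --out pred.tsv
chemtagger evaluate --gold corpus/gold.tsv --pred pred.tsv
chemtagger curate-dict --in raw.tsv --out lexicon.txt --audit audit.tsv
```

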