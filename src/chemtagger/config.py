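"""Declarative resource manifest.

A manifest is a YAML file naming every grammar and dictionary the
pipeline should scan with, in priority order::

    builtin: false
    resources:
      - name: drug
        kind: lexicon              # lexicon | grammar
        file: drug.txt             # one term per line / grammar dialect
        class: drug
        role: matching             # matching | blocking
        case_policy: first-insensitive
        token_boundary: false
        correction:
          enabled: true
          max_unparameterized_edits: 1
          min_entity_length: 4
      - name: cas_number
        kind: grammar
        file: cas.grammar
        class: cas_number
    include_list: include.txt      # optional, ordinary lexicon files
    stop_list: stop.txt            # optional

``builtin: true`` loads the shipped demonstrative resource set instead
(extra file-based resources are appended after it).  Relative paths are
resolved against the manifest's directory.  Errors name the offending
resource.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .correction import CorrectionConfig
from .engine import Resource, ResourceSet
from .grammar import compile_grammar, parse_grammar
from .lexicon import Lexicon, load_term_file

__all__ = ["load_manifest", "ManifestError"]


class ManifestError(ValueError):
    """Bad manifest content; message names the resource and field."""


def _load_lexicon(entry: dict, base: Path) -> Lexicon:
    terms, cs = load_term_file(base / entry["file"])
    if not terms:
        raise ManifestError(f"resource {entry['name']!r}: empty term file")
    return Lexicon(
        name=entry["name"],
        terms=terms,
        entity_class=entry.get("class", "chemical"),
        case_policy=entry.get("case_policy", "first-insensitive"),
        role=entry.get("role", "matching"),
        token_boundary=bool(entry.get("token_boundary", False)),
        case_sensitive_terms=cs,
    )


def _load_resource(entry: dict, base: Path) -> Resource:
    for key in ("name", "kind", "file"):
        if key not in entry:
            raise ManifestError(
                f"resource entry {entry.get('name', '?')!r}: missing {key!r}")
    correction = None
    if "correction" in entry:
        try:
            correction = CorrectionConfig(**entry["correction"])
        except (TypeError, ValueError) as exc:
            raise ManifestError(
                f"resource {entry['name']!r}: bad correction config: {exc}")
    kind = entry["kind"]
    if kind == "lexicon":
        lex = _load_lexicon(entry, base)
        return Resource(name=entry["name"], matcher=lex,
                        entity_class=lex.entity_class, role=lex.role,
                        correction=correction,
                        is_sum_formula=bool(entry.get("sum_formula", False)))
    if kind == "grammar":
        source = (base / entry["file"]).read_text(encoding="utf-8")
        automaton = compile_grammar(parse_grammar(source, entry.get("root")))
        return Resource(name=entry["name"], matcher=automaton,
                        entity_class=entry.get("class", "chemical"),
                        role=entry.get("role", "matching"),
                        correction=correction,
                        is_sum_formula=bool(entry.get("sum_formula", False)))
    raise ManifestError(f"resource {entry['name']!r}: unknown kind {kind!r}")


def load_manifest(path: str | Path) -> ResourceSet:
    path = Path(path)
    base = path.parent
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if data.get("builtin"):
        from .fixtures import builtin_resources
        rs = builtin_resources()
        resources = rs.resources
    else:
        resources = []
    for entry in data.get("resources", []) or []:
        resources.append(_load_resource(entry, base))
    if not resources:
        raise ManifestError("manifest defines no resources")

    def _opt_lexicon(key: str, cls: str) -> Lexicon | None:
        if key not in data or not data[key]:
            return None
        terms, cs = load_term_file(base / data[key])
        return Lexicon(name=key, terms=terms, entity_class=cls,
                       case_policy="first-insensitive",
                       case_sensitive_terms=cs)

    return ResourceSet(
        resources=resources,
        include_list=_opt_lexicon("include_list", "chemical"),
        stop_list=_opt_lexicon("stop_list", "chemical"),
    )
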