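"""Mention-level evaluation and include-list derivation.

Scores are micro-averaged: true/false positives and false negatives are
pooled over every document and section before precision, recall and the
F1 score are formed.  A prediction is a true positive iff a gold
annotation with the identical (document, section, start, end) exists;
entity-class labels are carried in the files for auditing but ignored
for matching, as in mention-level community evaluations.

File dialects (tab-separated, UTF-8):

* gold:        doc_id, T|A, start, end, text, class
* predictions: doc_id, "T:start:end" or "A:start:end", rank, confidence

Both readers/writers round-trip and the CLI evaluates one file against
the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .entities import Entity

__all__ = [
    "GoldAnnotation",
    "EvalResult",
    "evaluate",
    "derive_include_list",
    "read_gold_tsv", "write_gold_tsv",
    "read_predictions_tsv", "write_predictions_tsv",
]

logger = logging.getLogger(__name__)

GOLD_COLUMNS = ["doc_id", "section", "start", "end", "text", "entity_class"]
PRED_COLUMNS = ["doc_id", "location", "rank", "confidence"]


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    section_label: str          # T | A
    span: tuple[int, int]
    text: str
    entity_class: str = "chemical"

    @property
    def key(self) -> tuple:
        return (self.doc_id, self.section_label, self.span[0], self.span[1])


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __str__(self) -> str:
        return (f"tp={self.tp} fp={self.fp} fn={self.fn} "
                f"P={self.precision:.4f} R={self.recall:.4f} F1={self.f1:.4f}")


def _pred_key(e) -> tuple:
    if isinstance(e, Entity):
        return (e.doc_id, e.section_label, e.span[0], e.span[1])
    return e.key  # GoldAnnotation doubles as a prediction for sanity checks


def evaluate(pred, gold) -> EvalResult:
    """Micro-averaged exact-span scores of predictions against gold.

    Duplicate identical predictions are counted once (with a warning);
    each gold annotation can be matched by at most one prediction.
    """
    pred = list(pred)
    gold = list(gold)
    pred_keys = []
    seen = set()
    for e in pred:
        k = _pred_key(e)
        if k in seen:
            logger.warning("duplicate prediction %s counted once", k)
            continue
        seen.add(k)
        pred_keys.append(k)
    gold_keys = {g.key for g in gold}
    if len(gold_keys) != len(gold):
        logger.warning("duplicate gold annotations collapsed")
    tp = sum(1 for k in pred_keys if k in gold_keys)
    fp = len(pred_keys) - tp
    fn = len(gold_keys) - tp
    return EvalResult(tp=tp, fp=fp, fn=fn)


def derive_include_list(candidate_terms: list[tuple[str, int]], corpus,
                        gold, run_pipeline) -> list[str]:
    """Greedy include-list selection.

    ``candidate_terms`` are (term, false-negative count) pairs —
    typically the texts of the system's false negatives.  Candidates
    are visited by descending count (ties lexicographic); one is kept
    iff adding it to the include list strictly increases micro-F1 of
    ``run_pipeline(corpus, include_terms)`` on the gold standard.
    Ambiguous strings that hurt precision more than they help recall
    are thereby dropped.
    """
    accepted: list[str] = []
    base = evaluate(run_pipeline(corpus, accepted), gold)
    best_f1 = base.f1
    for term, _count in sorted(candidate_terms, key=lambda tc: (-tc[1], tc[0])):
        trial = evaluate(run_pipeline(corpus, accepted + [term]), gold)
        if trial.f1 > best_f1:
            accepted.append(term)
            best_f1 = trial.f1
    return accepted


# ---------------------------------------------------------------------------
# file dialects

def read_gold_tsv(path: str | Path) -> list[GoldAnnotation]:
    df = pd.read_csv(path, sep="\t", names=GOLD_COLUMNS, header=None,
                     dtype={"doc_id": str, "text": str}, keep_default_na=False)
    return [
        GoldAnnotation(row.doc_id, row.section, (int(row.start), int(row.end)),
                       row.text, row.entity_class)
        for row in df.itertuples()
    ]


def write_gold_tsv(annotations, path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.doc_id, a.section_label, a.span[0], a.span[1], a.text,
          a.entity_class) for a in annotations],
        columns=GOLD_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False)


def write_predictions_tsv(entities, path: str | Path) -> None:
    """CHEMDNER-dialect prediction file.  Rank is positional and the
    confidence constant: the system does not score its matches."""
    rows = []
    by_doc: dict[str, int] = {}
    for e in entities:
        by_doc[e.doc_id] = by_doc.get(e.doc_id, 0) + 1
        rows.append((e.doc_id, f"{e.section_label}:{e.span[0]}:{e.span[1]}",
                     by_doc[e.doc_id], 1.0))
    pd.DataFrame(rows, columns=PRED_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False)


def read_predictions_tsv(path: str | Path) -> list[GoldAnnotation]:
    """Read predictions into comparable records (text/class unknown)."""
    df = pd.read_csv(path, sep="\t", names=PRED_COLUMNS, header=None,
                     dtype={"doc_id": str, "location": str},
                     keep_default_na=False)
    out = []
    for row in df.itertuples():
        section, start, end = row.location.split(":")
        out.append(GoldAnnotation(row.doc_id, section, (int(start), int(end)),
                                  text="", entity_class=""))
    return out
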