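"""Precision/recall evaluation with the negative-abstract exemption.

Recall for abstract screening is estimated against gold-positive documents,
but a positive document whose site information lives only in the full text
(``info_in_abstract`` false) cannot be recovered from its abstract; such
documents are *exempted* — counted neither as false negatives nor anywhere
else — rather than penalising the screen for information it never saw.

Event-level scoring matches predicted against gold events greedily, one to
one, within each document, under one of two policies: ``trigger+residue``
(PTM class and residue identity must agree) or ``trigger+residue+positions``
(additionally, exact set equality of extracted positions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .extraction import PTMEvent


@dataclass
class GoldEvent:
    ptm: str
    residue: str
    positions: List[int] = field(default_factory=list)


@dataclass
class GoldLabel:
    doc_id: str
    ptm: str
    label: str                      # "positive" | "negative"
    info_in_abstract: Optional[bool] = None
    events: List[GoldEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")
        if self.label == "positive" and self.info_in_abstract is None:
            raise ValueError(
                f"{self.doc_id}: info_in_abstract required for positives")


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    exempted: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


def read_gold_labels(path: str | Path) -> List[GoldLabel]:
    """Gold-label JSONL: doc_id, ptm, label, info_in_abstract, events[]."""
    out: List[GoldLabel] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(GoldLabel(
                doc_id=str(rec["doc_id"]), ptm=rec["ptm"],
                label=rec["label"],
                info_in_abstract=rec.get("info_in_abstract"),
                events=[GoldEvent(ptm=e["ptm"], residue=e["residue"],
                                  positions=list(e.get("positions", [])))
                        for e in rec.get("events", [])]))
    return out


def evaluate_abstract_triage(predictions: Dict[str, bool],
                             gold: Sequence[GoldLabel],
                             ptm: str) -> EvalResult:
    """Document-level screening evaluation for one PTM class.

    tp: retrieved ∧ positive; fp: retrieved ∧ negative;
    fn: missed ∧ positive ∧ info in abstract;
    exempted: missed ∧ positive ∧ info only in full text.
    """
    labels = {g.doc_id: g for g in gold if g.ptm == ptm}
    unlabeled = sorted(set(predictions) - set(labels))
    if unlabeled:
        raise ValueError(f"predictions without gold labels: {unlabeled}")
    tp = fp = fn = exempted = 0
    for doc_id, g in labels.items():
        retrieved = predictions.get(doc_id, False)
        if retrieved:
            if g.label == "positive":
                tp += 1
            else:
                fp += 1
        elif g.label == "positive":
            if g.info_in_abstract:
                fn += 1
            else:
                exempted += 1
    return EvalResult(tp=tp, fp=fp, fn=fn, exempted=exempted)


def _event_matches(pred: PTMEvent, gold: GoldEvent, policy: str) -> bool:
    if pred.ptm != gold.ptm:
        return False
    residues = {s.residue for s in pred.sites}
    if gold.residue not in residues:
        return False
    if policy == "trigger+residue":
        return True
    pred_positions = set()
    for s in pred.sites:
        if s.residue == gold.residue:
            pred_positions.update(s.positions)
    return pred_positions == set(gold.positions)


def evaluate_events(predicted: Sequence[PTMEvent],
                    gold: Sequence[GoldLabel],
                    match_policy: str = "trigger+residue") -> EvalResult:
    """Greedy one-to-one event matching within each document."""
    if match_policy not in ("trigger+residue", "trigger+residue+positions"):
        raise ValueError(f"unknown policy {match_policy!r}")
    gold_by_doc: Dict[str, List[GoldEvent]] = {}
    for g in gold:
        gold_by_doc.setdefault(g.doc_id, []).extend(g.events)
    pred_by_doc: Dict[str, List[PTMEvent]] = {}
    for ev in predicted:
        pred_by_doc.setdefault(ev.doc_id, []).append(ev)

    tp = fp = fn = 0
    for doc_id in sorted(set(gold_by_doc) | set(pred_by_doc)):
        remaining = list(gold_by_doc.get(doc_id, []))
        for ev in pred_by_doc.get(doc_id, []):
            match = next((g for g in remaining
                          if _event_matches(ev, g, match_policy)), None)
            if match is not None:
                remaining.remove(match)
                tp += 1
            else:
                fp += 1
        fn += len(remaining)
    return EvalResult(tp=tp, fp=fp, fn=fn)
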