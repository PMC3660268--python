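"""Gene/protein mention tagging and ranking.

Tagging is pluggable: any callable mapping text to ``(start, end)`` spans can
stand in for an external tagger (spans can also be supplied from a
tab-separated exchange file).  The built-in heuristic tags tokens with
gene-name orthography — all-caps symbols of length 2–6 (STAT3, JAK2), tokens
mixing case or letters and digits with an internal capital or digit (hBVR,
NbaA, PKCdelta) — plus optional dictionary names.

Candidates are ranked by a three-component additive score: +1 if the surface
form occurs in a sentence that produced a PTM event, +1 if it occurs in the
title, +1 if it is (one of) the most frequent form(s) in the document.
Surface forms are grouped by case-insensitive string equality only; no
normalisation to database identifiers is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from .corpus_io import Document
from .extraction import PTMEvent

logger = logging.getLogger(__name__)

#: Everyday all-caps tokens that are not gene symbols.
ALLCAPS_BLOCKLIST = frozenset({
    "DNA", "RNA", "MRNA", "ATP", "ADP", "AMP", "GTP", "GDP", "NAD", "NADH",
    "NADP", "PCR", "HPLC", "SDS", "PAGE", "MS", "LC", "UV", "PH", "CPG",
    "USA", "II", "III", "IV", "VI", "PTM", "PTMS", "OST", "ELISA", "EDTA",
    "KDA", "RPM", "CO", "AND", "THE", "FOR", "NOT", "WAS",
})

#: Residue-style compact tokens (S21, T33) are never gene mentions.
_RESIDUE_COMPACT = re.compile(r"^[A-Z]\d+$")

_TOKEN = re.compile(r"[A-Za-z][A-Za-z0-9]*")


@dataclass
class GeneMention:
    surface: str
    span: Tuple[int, int]
    section_label: str = ""
    sentence_index: int = 0


@dataclass
class RankedGene:
    surface: str          # representative (first-seen) surface form
    key: str              # case-normalised grouping key
    score: int
    rank: int
    evidence: Dict[str, bool] = field(default_factory=dict)
    count: int = 0


def _looks_like_gene(token: str) -> bool:
    if len(token) < 2 or token.isdigit():
        return False
    if _RESIDUE_COMPACT.match(token):
        return False
    if token.isupper():
        return (2 <= len(token) <= 6
                and token not in ALLCAPS_BLOCKLIST
                and any(c.isalpha() for c in token))
    # mixed orthography: an uppercase letter or digit after the first
    # character, and not a plain Capitalised word
    has_inner_upper = any(c.isupper() for c in token[1:])
    has_digit = any(c.isdigit() for c in token)
    plain_capitalised = token[0].isupper() and token[1:].islower()
    if plain_capitalised and not has_digit:
        return False
    if token.islower() and not has_digit:
        return False
    return has_inner_upper or has_digit


def heuristic_tagger(text: str) -> List[Tuple[int, int]]:
    """Built-in orthography-based tagger: text in, mention spans out."""
    spans = []
    for m in _TOKEN.finditer(text):
        if _looks_like_gene(m.group(0)):
            spans.append(m.span())
    return spans


class DictionaryTagger:
    """Tagger matching an explicit name list (word-boundary,
    case-insensitive) in addition to the orthographic heuristic."""

    def __init__(self, names: Iterable[str], use_heuristic: bool = True):
        escaped = sorted((re.escape(n) for n in names), key=len, reverse=True)
        self._pat = re.compile(r"\b(?:" + "|".join(escaped) + r")\b",
                               re.IGNORECASE) if escaped else None
        self._use_heuristic = use_heuristic

    def __call__(self, text: str) -> List[Tuple[int, int]]:
        spans = list(heuristic_tagger(text)) if self._use_heuristic else []
        if self._pat is not None:
            for m in self._pat.finditer(text):
                if m.span() not in spans:
                    spans.append(m.span())
        return sorted(set(spans))


def read_tagger_exchange(path: str | Path) -> Dict[str, List[Tuple[int, int, str]]]:
    """Read an external tagger's output: tab-separated
    ``doc_id  start  end  surface`` lines, grouped by doc_id."""
    out: Dict[str, List[Tuple[int, int, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, start, end, surface = line.split("\t")[:4]
            out.setdefault(doc_id, []).append((int(start), int(end), surface))
    return out


Tagger = Callable[[str], Sequence[Tuple[int, int]]]


def tag_gene_mentions(doc: Document,
                      tagger: Optional[Tagger] = None) -> List[GeneMention]:
    """Tag candidate gene/protein mentions per sentence.

    A failing tagger yields an empty mention list and a logged flag; the
    document is otherwise processed normally.
    """
    tagger = tagger or heuristic_tagger
    mentions: List[GeneMention] = []
    for section in doc.sections:
        for sent in section.sentences:
            try:
                spans = tagger(sent.text)
            except Exception as exc:  # tagger contract violation
                logger.error("tagger failed on %s (%s); document flagged "
                             "untagged", doc.doc_id, exc)
                return []
            for start, end in spans:
                mentions.append(GeneMention(
                    surface=sent.text[start:end], span=(start, end),
                    section_label=section.label, sentence_index=sent.index))
    return mentions


def rank_gene_mentions(doc: Document, mentions: Sequence[GeneMention],
                       events: Sequence[PTMEvent]) -> List[RankedGene]:
    """Rank surface forms by the +1/+1/+1 score.

    Ties in frequency all receive the most-frequent credit; ties in score are
    broken by earliest first mention in document order; ranks are 1..n.
    """
    if not mentions:
        return []
    event_sentences = {(ev.section_label, ev.sentence_index) for ev in events}
    sec_index = {sec.label: i for i, sec in enumerate(doc.sections)}

    groups: Dict[str, List[GeneMention]] = {}
    for m in mentions:
        groups.setdefault(m.surface.lower(), []).append(m)

    max_count = max(len(v) for v in groups.values())
    ranked: List[RankedGene] = []
    for key, group in groups.items():
        in_event = any((m.section_label, m.sentence_index) in event_sentences
                       for m in group)
        in_title = any(m.section_label == "title" for m in group)
        most_freq = len(group) == max_count
        keyed = sorted(group, key=lambda m: (sec_index.get(m.section_label, 99),
                                             m.sentence_index, m.span[0]))
        first = (sec_index.get(keyed[0].section_label, 99),
                 keyed[0].sentence_index, keyed[0].span[0])
        ranked.append(RankedGene(
            surface=keyed[0].surface, key=key,
            score=int(in_event) + int(in_title) + int(most_freq),
            rank=0,
            evidence={"in_ptm_sentence": in_event, "in_title": in_title,
                      "most_frequent": most_freq},
            count=len(group),
        ))
        ranked[-1]._first = first  # type: ignore[attr-defined]
    ranked.sort(key=lambda g: (-g.score, g._first))  # type: ignore[attr-defined]
    for i, g in enumerate(ranked, start=1):
        g.rank = i
        del g._first  # type: ignore[attr-defined]
    return ranked
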