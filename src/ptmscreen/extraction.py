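"""Three-step PTM event extraction.

1. *Triage*: a document is screened for the presence of the per-class
   filtering tokens (bare substrings like ``phospho``); documents with no
   token are dropped.
2. *Trigger matching*: each sentence is checked against the fine-grained
   trigger patterns of the classes that survived triage; matches are vetoed
   by class-specific stop terms (chemical-name contexts such as
   O-acetylserine) and by document-context rules (DNA/CpG methylation).
3. *Site detection and position parsing*: a sentence is retained only if it
   also names a modifiable amino acid (or a protein terminus, or a generic
   "site"/"residue" term).  Sequence positions are recovered by shallow
   preposition-based parsing — scanning from the residue mention through an
   unbroken chain of linking elements (prepositions, punctuation,
   conjunctions, digits) — never by syntactic parsing.  Position extraction
   is optional: a residue mention without coordinates still yields an event,
   except under the abstract-screening rule for phosphorylation, where a
   sentence must carry a sequence position to be retained.

Because no syntactic dependency between trigger and site is required, some
co-mention false positives are accepted by design (e.g. a title naming both
"cysteine-containing" and "disulfide-bonded" yields a disulfide event).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .corpus_io import Document, Sentence
from .lexicon import PTMClass, PTMLexicon, STOP_TERM_WINDOW
from .residues import AMINO_ACIDS, FULL_TO_ONE, FULL_TO_THREE, ONE_TO_FULL

logger = logging.getLogger(__name__)

MAX_POSITION = 99999  # larger integers are never sequence positions


@dataclass
class TriggerMatch:
    ptm: str
    span: Tuple[int, int]
    surface: str


@dataclass
class SiteMention:
    residue: str                # full name, "N-terminus", "C-terminus", "generic"
    span: Tuple[int, int]
    positions: List[int] = field(default_factory=list)


@dataclass
class PTMEvent:
    doc_id: str
    section_label: str
    sentence_index: int
    sentence_text: str
    ptm: str
    trigger: TriggerMatch
    sites: List[SiteMention]

    def all_positions(self) -> List[int]:
        seen: List[int] = []
        for s in self.sites:
            for p in s.positions:
                if p not in seen:
                    seen.append(p)
        return seen

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "section": self.section_label,
            "sentence_index": self.sentence_index,
            "sentence": self.sentence_text,
            "ptm": self.ptm,
            "trigger": {"start": self.trigger.span[0],
                        "end": self.trigger.span[1],
                        "text": self.trigger.surface},
            "sites": [{"residue": s.residue, "start": s.span[0],
                       "end": s.span[1], "positions": s.positions}
                      for s in self.sites],
        }


# ---------------------------------------------------------------------------
# Step 1: triage
# ---------------------------------------------------------------------------

def triage_document(doc: Document, lexicon: PTMLexicon) -> Set[str]:
    """Return the PTM classes whose filtering tokens occur (case-insensitive,
    unanchored substring) anywhere in the document.  Empty set ⇒ the document
    is dropped from further processing."""
    text = doc.text.lower()
    return {name for name, cls in lexicon.classes.items()
            if any(tok in text for tok in cls.filtering_tokens)}


def _section_has_token(section_text: str, cls: PTMClass) -> bool:
    low = section_text.lower()
    return any(tok in low for tok in cls.filtering_tokens)


# ---------------------------------------------------------------------------
# Step 2: trigger matching with vetoes
# ---------------------------------------------------------------------------

def _merge_spans(spans: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping/touching spans, keeping the widest extent."""
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _span_gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Character gap between two spans; 0 when they overlap or abut."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(b[0] - a[1], a[0] - b[1], 0)


def _find_cues(text: str, cue: str) -> List[Tuple[int, int]]:
    """Case-insensitive occurrences of a cue; single-word cues are matched at
    word boundaries, phrases as literal substrings."""
    if re.fullmatch(r"[\w-]+", cue):
        pat = re.compile(r"\b" + re.escape(cue) + r"\b", re.IGNORECASE)
    else:
        pat = re.compile(re.escape(cue), re.IGNORECASE)
    return [m.span() for m in pat.finditer(text)]


def match_ptm_sentence(sentence: Sentence, ptm: PTMClass,
                       lexicon: PTMLexicon) -> List[TriggerMatch]:
    """Trigger matches for one class in one sentence, after stop-term and
    context-rule vetoes.  Overlapping matches are merged to the longest span."""
    text = sentence.text
    raw: List[Tuple[int, int]] = []
    for pat in ptm.compiled_triggers():
        raw.extend(m.span() for m in pat.finditer(text))
    if not raw:
        return []
    spans = _merge_spans(raw)

    # class-specific stop terms: veto when the term overlaps or lies within
    # a small window of the trigger span (appositive-scale neighbourhood)
    stop_spans: List[Tuple[int, int]] = []
    for term in ptm.stop_terms:
        stop_spans.extend(_find_cues(text, term))
    survivors = [s for s in spans
                 if not any(_span_gap(s, ss) <= STOP_TERM_WINDOW
                            for ss in stop_spans)]

    # document-context exclusions (e.g. DNA methylation): veto unless a
    # modifiable residue mention lies closer to the trigger than every cue
    for rule in lexicon.global_exclusions:
        if rule.ptm != ptm.name or not survivors:
            continue
        cue_spans: List[Tuple[int, int]] = []
        for cue in rule.cues:
            cue_spans.extend(_find_cues(text, cue))
        if not cue_spans:
            continue
        residue_spans = [m.span for m in _residue_mentions(text, ptm)]
        kept = []
        for s in survivors:
            cue_d = min(_span_gap(s, c) for c in cue_spans)
            res_d = min((_span_gap(s, r) for r in residue_spans),
                        default=None)
            if res_d is not None and res_d < cue_d:
                kept.append(s)
        survivors = kept

    return [TriggerMatch(ptm=ptm.name, span=s, surface=text[s[0]:s[1]])
            for s in survivors]


# ---------------------------------------------------------------------------
# Step 3a: site mentions
# ---------------------------------------------------------------------------

_N_TERM = re.compile(r"\b(?:N|amino)[-\s]termin(?:us|al|i)\b", re.IGNORECASE)
_C_TERM = re.compile(r"\b(?:C|carboxyl?)[-\s]termin(?:us|al|i)\b",
                     re.IGNORECASE)

_RESIDUE_RE_CACHE: Dict[Tuple[str, ...], List[Tuple[re.Pattern, Optional[str]]]] = {}


def _residue_patterns(ptm: PTMClass) -> List[Tuple[re.Pattern, Optional[str]]]:
    """Compiled mention patterns for a class's allowed residues.

    Spelled-out names match case-insensitively with an optional attached
    compact position ("serine-21").  Three-letter codes must be capitalised
    (Ser, His — never the pronoun "his"), optionally phospho-prefixed and with
    an attached number ("pSer21", "Ser-15").  One-letter codes are accepted
    only when immediately followed by digits ("S21"); a bare "S" is never a
    residue mention.
    """
    key = tuple(ptm.allowed_residues)
    if key in _RESIDUE_RE_CACHE:
        return _RESIDUE_RE_CACHE[key]
    pats: List[Tuple[re.Pattern, Optional[str]]] = []
    for full in ptm.allowed_residues:
        three = FULL_TO_THREE[full]
        one = FULL_TO_ONE[full]
        pats.append((re.compile(
            r"\b" + full + r"s?(?:-(\d{1,5}))?\b", re.IGNORECASE), full))
        pats.append((re.compile(
            r"\b(?:p)?" + three + r"(?:-?(\d{1,5}))?\b"), full))
        pats.append((re.compile(
            r"\b(?:p)?" + one + r"(\d{1,5})\b"), full))
    _RESIDUE_RE_CACHE[key] = pats
    return pats


def _residue_mentions(text: str, ptm: PTMClass) -> List[SiteMention]:
    found: List[SiteMention] = []
    taken: List[Tuple[int, int]] = []
    matches = []
    for pat, full in _residue_patterns(ptm):
        for m in pat.finditer(text):
            matches.append((m.start(), -(m.end() - m.start()), m, full))
    # leftmost-longest wins among overlapping matches
    for _, _, m, full in sorted(matches, key=lambda t: (t[0], t[1])):
        span = m.span()
        if any(span[0] < e and s < span[1] for s, e in taken):
            continue
        taken.append(span)
        compact = [int(g) for g in m.groups() if g]
        found.append(SiteMention(residue=full, span=span, positions=compact))
    found.sort(key=lambda s: s.span)
    return found


def detect_site_mentions(sentence: Sentence, ptm: PTMClass,
                         lexicon: PTMLexicon) -> List[SiteMention]:
    """Residue, terminus, and generic-site mentions in a sentence.

    One mention per residue occurrence; terminus mentions only where the
    class allows them; generic "site"/"residue" mentions only when no
    concrete residue mention exists."""
    text = sentence.text
    mentions = _residue_mentions(text, ptm)
    if ptm.terminus_allowed.get("n"):
        mentions.extend(SiteMention(residue="N-terminus", span=m.span())
                        for m in _N_TERM.finditer(text))
    if ptm.terminus_allowed.get("c"):
        mentions.extend(SiteMention(residue="C-terminus", span=m.span())
                        for m in _C_TERM.finditer(text))
    if not mentions:
        generic = re.compile(
            r"\b(?:" + "|".join(re.escape(t) for t in
                                lexicon.generic_site_terms) + r")\b",
            re.IGNORECASE)
        mentions = [SiteMention(residue="generic", span=m.span())
                    for m in generic.finditer(text)]
    mentions.sort(key=lambda s: s.span)
    return mentions


# ---------------------------------------------------------------------------
# Step 3b: preposition-based position parsing
# ---------------------------------------------------------------------------

_NUM = re.compile(r"\d{1,6}")
_RANGE = re.compile(r"\b(\d{1,5})\s*[-–]\s*(\d{1,5})\b")
_POSITIONAL_NOUNS = {"position", "positions", "site", "sites",
                     "residue", "residues"}


def _tokenize(text: str) -> List[Tuple[int, int, str]]:
    return [(m.start(), m.end(), m.group(0))
            for m in re.finditer(r"\d+|[A-Za-z]+|[^\sA-Za-z\d]", text)]


def _is_link(tok: str, linking: Set[str]) -> bool:
    if tok.lower() in linking:
        return True
    return tok in {",", ";", "/", "-", "–", "(", ")"}


def parse_positions(sentence_text: str, site: SiteMention,
                    lexicon: PTMLexicon) -> SiteMention:
    """Fill ``site.positions`` by shallow chain parsing.

    Rightward from the mention, the scan walks an unbroken chain of linking
    elements — linking terms ("position", "at", …), digits, commas, "and"/
    "or", slashes, hyphens — collecting every integer until the first
    non-linking token.  The mirrored leftward scan ("position 21 of the
    serine residue…") additionally requires the number chain to be introduced
    by a positional noun, so bare counts ("the 5 serine residues") are not
    misread as coordinates.  Compact positions attached to the mention itself
    (Ser-15, S21) are kept.  Numeric ranges contribute their two endpoints
    only.  Positions are 1-based; 0 and oversized integers are skipped with a
    warning; duplicates collapse, first-occurrence order kept.
    """
    linking = {t.lower() for t in lexicon.linking_terms}
    tokens = _tokenize(sentence_text)

    def collect(number_tokens: Iterable[str]) -> List[int]:
        out = []
        for tok in number_tokens:
            val = int(tok)
            if val < 1 or val > MAX_POSITION:
                logger.warning("position token %r out of range, skipped", tok)
                continue
            out.append(val)
        return out

    # rightward chain
    right_nums: List[str] = []
    idx = next((i for i, (s, e, _) in enumerate(tokens) if s >= site.span[1]),
               len(tokens))
    for s, e, tok in tokens[idx:]:
        if tok.isdigit():
            right_nums.append(tok)
        elif not _is_link(tok, linking):
            break

    # mirrored leftward chain, gated on a positional noun introducing it
    left_nums: List[str] = []
    left_tokens = [t for t in tokens if t[1] <= site.span[0]]
    pending: List[str] = []
    introduced = False
    for s, e, tok in reversed(left_tokens):
        if tok.isdigit():
            pending.append(tok)
        elif tok.lower() in _POSITIONAL_NOUNS and pending:
            introduced = True
            break
        elif not _is_link(tok, linking):
            break
    if introduced:
        left_nums = list(reversed(pending))

    if _RANGE.search(sentence_text):
        logger.warning("numeric range near %r: endpoints only are kept",
                       sentence_text[site.span[0]:site.span[1]])

    ordered = collect(left_nums) + list(site.positions) + collect(right_nums)
    deduped: List[int] = []
    for p in ordered:
        if p not in deduped:
            deduped.append(p)
    site.positions = deduped
    return site


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def extract_events(doc: Document, lexicon: PTMLexicon,
                   mode: str = "abstract_screen") -> List[PTMEvent]:
    """Run triage → trigger matching → site detection → position parsing.

    Modes: ``abstract_screen`` applies the position-required rule for classes
    flagged with it (phosphorylation by default); ``fulltext`` screens each
    section independently for filtering tokens and carries section labels;
    ``unrestricted`` never requires positions.  Deterministic and idempotent.
    """
    if mode not in ("abstract_screen", "fulltext", "unrestricted"):
        raise ValueError(f"unknown mode {mode!r}")
    classes = triage_document(doc, lexicon)
    events: List[PTMEvent] = []
    for section in doc.sections:
        for name in sorted(classes):
            cls = lexicon.classes[name]
            if mode == "fulltext" and not _section_has_token(section.text, cls):
                continue
            for sent in section.sentences:
                triggers = match_ptm_sentence(sent, cls, lexicon)
                if not triggers:
                    continue
                sites = detect_site_mentions(sent, cls, lexicon)
                if not sites:
                    continue
                sites = [parse_positions(sent.text, s, lexicon) for s in sites]
                if (mode == "abstract_screen"
                        and cls.position_required_in_abstract_screen
                        and not any(s.positions for s in sites)):
                    continue
                for trig in triggers:
                    events.append(PTMEvent(
                        doc_id=doc.doc_id,
                        section_label=section.label,
                        sentence_index=sent.index,
                        sentence_text=sent.text,
                        ptm=name,
                        trigger=trig,
                        sites=[SiteMention(residue=s.residue, span=s.span,
                                           positions=list(s.positions))
                               for s in sites],
                    ))
    return events


def write_events_jsonl(events: Iterable[PTMEvent], path) -> None:
    import json
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict(), ensure_ascii=False) + "\n")
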