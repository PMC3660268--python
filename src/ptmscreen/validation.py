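"""Cross-validation of extracted phosphosites against annotated sites.

An annotation table row carries a protein accession, its gene/protein names,
species, the phosphorylated residue (one-letter code), the 1-based position
in the canonical sequence, and a *mature offset* — the numbering shift
introduced by protein processing (e.g. signal-peptide cleavage), so a site at
canonical position 45 with offset 24 is reported as position 21 in papers
that number the mature chain.

Literature retrieval is expressed as declarative *query descriptors* (names
OR-joined, a species conjunct for non-human proteins, a synonym fallback
tier, a result cap); they are executed against a local corpus — no network
access.  For human targets the asymmetric species-exclusion filter drops any
abstract that mentions another species.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .corpus_io import Document
from .extraction import PTMEvent
from .residues import FULL_TO_ONE, ONE_TO_FULL

logger = logging.getLogger(__name__)

DEFAULT_QUERY_CAP = 20000
HUMAN_NAMES = {"human", "homo sapiens", "h. sapiens"}

#: Greek-letter spelling swaps used when generating morphological variants.
GREEK = {"alpha": "α", "beta": "β", "gamma": "γ",
         "delta": "δ", "epsilon": "ε", "kappa": "κ"}


@dataclass
class SiteAnnotation:
    accession: str
    names: List[str]
    species: str
    residue: str           # one-letter code
    position: int
    mature_offset: int = 0
    evidence: str = ""


@dataclass
class ValidationHit:
    accession: str
    residue: str
    position: int
    matched_position: int
    offset_applied: bool
    doc_id: str
    section_label: str
    sentence_index: int
    sentence_text: str
    matched_name: str = ""


@dataclass
class QueryDescriptor:
    """Declarative per-protein literature query (never executed online)."""
    terms: List[str]
    species_conjunct: Optional[str]      # set for non-human proteins
    species_postfilter: bool             # exclusion filter, human only
    synonym_fallback: List[str] = field(default_factory=list)
    cap: int = DEFAULT_QUERY_CAP


def load_site_annotations(path: str | Path) -> List[SiteAnnotation]:
    """Read the annotation TSV (columns accession, names, species, residue,
    position, mature_offset, evidence); invalid rows are rejected with a
    logged reason, duplicate (accession, residue, position) rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "names", "species", "residue", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out: List[SiteAnnotation] = []
    seen: Set[Tuple[str, str, int]] = set()
    for i, row in df.iterrows():
        residue = row["residue"].strip().upper()
        if residue not in ONE_TO_FULL:
            logger.error("row %d: bad residue code %r, rejected", i, residue)
            continue
        try:
            position = int(row["position"])
            offset = int(row.get("mature_offset", "0") or 0)
        except ValueError:
            logger.error("row %d: non-integer position/offset, rejected", i)
            continue
        if position < 1:
            logger.error("row %d: non-positive position %d, rejected",
                         i, position)
            continue
        if offset < 0:
            logger.error("row %d: negative mature_offset, rejected", i)
            continue
        names = [n.strip() for n in row["names"].split(";") if n.strip()]
        if not names:
            logger.error("row %d: empty names, rejected", i)
            continue
        key = (row["accession"], residue, position)
        if key in seen:
            continue
        seen.add(key)
        out.append(SiteAnnotation(
            accession=row["accession"], names=names,
            species=row["species"].strip(), residue=residue,
            position=position, mature_offset=offset,
            evidence=row.get("evidence", "")))
    return out


def load_two_column_tsv(path: str | Path) -> Dict[str, List[str]]:
    """name → synonyms table (species lexicon / gene synonym table)."""
    out: Dict[str, List[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            syn = parts[1].strip() if len(parts) > 1 else ""
            out.setdefault(name, [])
            if syn:
                out[name].append(syn)
    return out


def build_protein_query(annotation_names: Iterable[str], species: str,
                        synonym_table: Optional[Dict[str, List[str]]] = None,
                        cap: int = DEFAULT_QUERY_CAP) -> QueryDescriptor:
    """Build the declarative retrieval descriptor for one protein.

    Non-human proteins get a species conjunct in the query itself; human
    proteins instead enable the species-exclusion post-filter.  Synonyms from
    the table form the fallback tier used only when the primary terms
    retrieve nothing.
    """
    names = [n for n in annotation_names if n]
    if not names:
        raise ValueError("build_protein_query requires at least one name")
    is_human = species.strip().lower() in HUMAN_NAMES
    synonyms: List[str] = []
    for name in names:
        for syn in (synonym_table or {}).get(name, []):
            if syn not in names and syn not in synonyms:
                synonyms.append(syn)
    return QueryDescriptor(
        terms=list(names),
        species_conjunct=None if is_human else species.strip(),
        species_postfilter=is_human,
        synonym_fallback=synonyms,
        cap=cap,
    )


def _word_pat(term: str) -> re.Pattern:
    return re.compile(r"\b" + re.escape(term) + r"\b", re.IGNORECASE)


def execute_query_local(descriptor: QueryDescriptor,
                        docs: Sequence[Document]) -> List[Document]:
    """Run a query descriptor against a local corpus.

    A term individually matching more documents than the cap is dropped as
    non-specific (with a warning).  If the primary terms retrieve nothing the
    synonym fallback tier is tried.  The species conjunct, when present, is
    required as a co-occurring mention.
    """
    def retrieve(terms: List[str]) -> List[Document]:
        kept: List[Document] = []
        usable: List[str] = []
        for term in terms:
            n = sum(1 for d in docs if _word_pat(term).search(d.text))
            if n > descriptor.cap:
                logger.warning("term %r matches %d > %d documents, dropped",
                               term, n, descriptor.cap)
                continue
            usable.append(term)
        if not usable:
            return []
        species_pat = (_word_pat(descriptor.species_conjunct)
                       if descriptor.species_conjunct else None)
        for doc in docs:
            if any(_word_pat(t).search(doc.text) for t in usable):
                if species_pat is None or species_pat.search(doc.text):
                    kept.append(doc)
            if len(kept) >= descriptor.cap:
                break
        return kept

    hits = retrieve(descriptor.terms)
    if not hits and descriptor.synonym_fallback:
        hits = retrieve(descriptor.synonym_fallback)
    return hits


def species_exclusion_filter(doc: Document, target: str,
                             species_lexicon: Dict[str, List[str]]) -> bool:
    """Keep/drop decision for one document.

    Applied only when the target species is human (the query for non-human
    proteins is already species-constrained): the document is dropped iff it
    mentions any species other than the target.  Returns True to keep.
    """
    if target.strip().lower() not in HUMAN_NAMES:
        return True
    target_terms = {t.lower() for t in
                    (HUMAN_NAMES | {"humans", "patient", "patients"})}
    text = doc.text
    for name, synonyms in species_lexicon.items():
        for term in [name] + list(synonyms):
            if term.lower() in target_terms:
                continue
            if _word_pat(term).search(text):
                return False
    return True


# ---------------------------------------------------------------------------
# Morphological variants for co-mention checking
# ---------------------------------------------------------------------------

def morphological_variants(name: str) -> Set[str]:
    """Case, hyphen/space, plural and Greek-spelling variants of a name.
    All lowercase (matching is case-insensitive anyway)."""
    base = name.lower()
    variants = {base}
    variants.add(base.replace("-", " "))
    variants.add(base.replace(" ", "-"))
    variants.add(base.replace("-", "").replace(" ", ""))
    for spelled, letter in GREEK.items():
        for v in list(variants):
            if spelled in v:
                variants.add(v.replace(spelled, letter))
            if letter in v:
                variants.add(v.replace(letter, spelled))
    variants |= {v + "s" for v in variants}
    return variants


def _name_in_text(name: str, text: str) -> bool:
    low = text.lower()
    return any(re.search(r"\b" + re.escape(v) + r"\b", low)
               for v in morphological_variants(name))


def _event_residue_letters(residue: str) -> Optional[str]:
    if residue in ("N-terminus", "C-terminus"):
        return None
    if residue == "generic":
        return "*"
    return FULL_TO_ONE.get(residue)


def match_events_to_annotations(
        events: Sequence[PTMEvent],
        annotations: Sequence[SiteAnnotation],
        require_co_mention: bool = False,
        name_lexicon: Optional[Dict[str, List[str]]] = None,
        allow_generic: bool = True) -> List[ValidationHit]:
    """Emit a hit when an extracted site agrees with an annotated site.

    Agreement requires (a) residue compatibility — the event residue's
    one-letter code equals the annotated residue, or the event site is a
    generic "site"/"residue" mention (allowed by default) — and (b) an event
    position equal to the annotated canonical position, or to
    position − mature_offset (flagged as offset-applied).  At most one hit is
    emitted per (event, annotation, matched position).  With
    ``require_co_mention`` the event sentence must also contain one of the
    annotation's names (or a synonym from ``name_lexicon``, or an
    automatically generated morphological variant).
    """
    hits: List[ValidationHit] = []
    for ev in events:
        for ann in annotations:
            comention_name = ""
            if require_co_mention:
                candidates = list(ann.names)
                for n in ann.names:
                    candidates.extend((name_lexicon or {}).get(n, []))
                comention_name = next(
                    (n for n in candidates
                     if _name_in_text(n, ev.sentence_text)), "")
                if not comention_name:
                    continue
            emitted: Set[int] = set()
            for site in ev.sites:
                letter = _event_residue_letters(site.residue)
                if letter is None:
                    continue
                if letter == "*" and not allow_generic:
                    continue
                if letter not in ("*", ann.residue):
                    continue
                for pos in site.positions:
                    if pos in emitted:
                        continue
                    if pos == ann.position:
                        offset_applied = False
                    elif (ann.mature_offset > 0
                          and pos == ann.position - ann.mature_offset):
                        offset_applied = True
                    else:
                        continue
                    emitted.add(pos)
                    hits.append(ValidationHit(
                        accession=ann.accession, residue=ann.residue,
                        position=ann.position, matched_position=pos,
                        offset_applied=offset_applied, doc_id=ev.doc_id,
                        section_label=ev.section_label,
                        sentence_index=ev.sentence_index,
                        sentence_text=ev.sentence_text,
                        matched_name=comention_name or (ann.names[0]
                                                        if ann.names else "")))
    return hits
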