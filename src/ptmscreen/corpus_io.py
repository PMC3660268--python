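"""Document input: abstracts and full text, sectioning, sentence splitting.

Documents are modelled as an ordered list of labelled sections; each section
carries its raw text plus sentence offsets into that text.  Character offsets
are 0-based half-open throughout; protein sequence positions (elsewhere in the
package) are 1-based, following the UniProt convention.

Supported input formats:

* ``jsonl`` — one JSON object per line.  Abstracts use keys ``pmid``,
  ``title``, ``abstract``; pre-sectioned full text uses ``pmid``, ``title``,
  ``sections: [{"label": ..., "text": ...}]``.  JSONL is the canonical
  interchange dialect; the XML readers convert into the same in-memory form.
* ``pubmed_xml`` — MEDLINE/PubMed ``PubmedArticle`` records (PMID,
  ArticleTitle, AbstractText).
* ``fulltext_xml`` — JATS-like ``<sec><title>...</title><p>...</p></sec>``.
* ``fulltext_text`` — plain text (e.g. converted from PDF upstream),
  partitioned into sections by heading detection.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

SECTION_LABELS = ("title", "abstract", "introduction", "methods", "results",
                  "discussion", "unknown")

#: Heading strings (lowercased, punctuation-stripped) mapped to canonical
#: section labels.  "Results and Discussion" deliberately maps to discussion.
HEADING_MAP = {
    "introduction": "introduction",
    "background": "introduction",
    "materials and methods": "methods",
    "methods": "methods",
    "materials & methods": "methods",
    "experimental procedures": "methods",
    "results": "results",
    "results and discussion": "discussion",
    "discussion": "discussion",
}

#: Version-pinned abbreviation list for the sentence splitter.  A period that
#: closes one of these tokens never ends a sentence.  Single capital letters
#: ("T. Smith", initials) are handled separately.
ABBREVIATIONS = frozenset({
    "fig", "figs", "et al", "al", "e.g", "i.e", "vs", "cf", "ref", "refs",
    "eq", "eqs", "no", "nos", "vol", "approx", "ca", "etc", "dr", "st",
    "ser", "thr", "tyr", "cys", "lys", "arg", "his", "asn", "gln", "asp",
    "glu", "gly", "ala", "val", "leu", "ile", "pro", "phe", "met", "trp",
    "mol", "biol", "chem", "sci", "acad", "natl", "proc", "res", "wt",
})


@dataclass
class Sentence:
    """One sentence with half-open character offsets into its section text."""
    text: str
    start: int
    end: int
    index: int


@dataclass
class Section:
    label: str
    text: str
    sentences: List[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in SECTION_LABELS:
            raise ValueError(f"unknown section label: {self.label!r}")
        if not self.sentences:
            self.sentences = split_sentences(self.text)


@dataclass
class Document:
    doc_id: str
    title: str
    sections: List[Section]
    source_kind: str = "abstract"  # abstract | fulltext_xml | fulltext_plain

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def iter_sentences(self) -> Iterator[tuple[Section, Sentence]]:
        for sec in self.sections:
            for sent in sec.sentences:
                yield sec, sent

    @property
    def text(self) -> str:
        return "\n".join(sec.text for sec in self.sections)


def make_abstract_document(doc_id: str, title: str, abstract: str) -> Document:
    """Build an abstract Document: a title section (one atomic sentence) plus
    an abstract section.  Titles are not sentence-split: a title is one
    statement however many periods it contains."""
    title = title or ""
    title_sentences = (
        [Sentence(text=title, start=0, end=len(title), index=0)] if title else []
    )
    return Document(
        doc_id=doc_id,
        title=title,
        sections=[
            Section(label="title", text=title, sentences=title_sentences),
            Section(label="abstract", text=abstract or ""),
        ],
        source_kind="abstract",
    )


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_BOUNDARY = re.compile(r"[.?!]+")


def _is_abbreviation(text: str, period_pos: int) -> bool:
    """True if the token ending at ``period_pos`` is a known abbreviation or a
    single capital letter (an initial)."""
    m = re.search(r"[A-Za-z][A-Za-z.]*$", text[:period_pos])
    if not m:
        return False
    token = m.group(0).lower().rstrip(".")
    if token in ABBREVIATIONS:
        return True
    # "et al" spans two tokens
    if token == "al" and text[:period_pos].lower().rstrip().endswith("et al"):
        return True
    # single capital letter: an initial, "T." in "T. Smith"
    raw = m.group(0)
    return len(raw) == 1 and raw.isupper()


def split_sentences(text: str) -> List[Sentence]:
    """Split ``text`` into sentences.

    A boundary is a run of ``.?!`` followed by whitespace and an uppercase
    letter or digit, except when the period closes a known biomedical
    abbreviation or when the candidate lies inside unclosed parentheses or
    brackets.  Offsets are 0-based half-open into ``text``; joining the
    sentence substrings at their offsets reproduces the input exactly
    (inter-sentence gaps are pure whitespace).
    """
    if not text or not text.strip():
        return []
    boundaries: List[int] = []
    depth = 0
    for i, ch in enumerate(text):
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif ch in ".?!" and depth == 0:
            m = _BOUNDARY.match(text, i)
            end = m.end()
            if end >= len(text):
                continue
            # require whitespace then uppercase/digit
            j = end
            while j < len(text) and text[j].isspace():
                j += 1
            if j == end or j >= len(text):
                continue
            if not (text[j].isupper() or text[j].isdigit()):
                continue
            if ch == "." and _is_abbreviation(text, i):
                continue
            boundaries.append(end)
    sentences: List[Sentence] = []
    prev = 0
    for b in boundaries + [len(text)]:
        chunk = text[prev:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail_stripped = chunk.rstrip()
        if trail_stripped:
            start = prev + lead
            end = prev + len(chunk.rstrip())
            sentences.append(Sentence(text=text[start:end], start=start,
                                      end=end, index=len(sentences)))
        prev = b
    return sentences


# ---------------------------------------------------------------------------
# Plain-text sectioning
# ---------------------------------------------------------------------------

def sectionize_plaintext(text: str) -> List[Section]:
    """Partition full-article plain text into canonical sections.

    A line consisting (case-insensitively, ignoring surrounding whitespace,
    trailing punctuation and a leading number) of a recognised heading opens a
    new section; material before the first heading, and headings we do not
    recognise, accumulate into ``unknown`` sections.  Every input character
    belongs to exactly one section.
    """
    if not text:
        raise ValueError("sectionize_plaintext requires non-empty text")
    lines = text.splitlines(keepends=True)
    sections: List[Section] = []
    cur_label = "unknown"
    cur_start = 0
    pos = 0

    def flush(end: int) -> None:
        nonlocal cur_start
        chunk = text[cur_start:end]
        if chunk:
            sections.append(Section(label=cur_label, text=chunk))
        cur_start = end

    for line in lines:
        stripped = re.sub(r"^[\d.\s]+", "", line.strip())
        key = stripped.rstrip(" :.").lower()
        if key in HEADING_MAP:
            flush(pos)
            cur_label = HEADING_MAP[key]
        pos += len(line)
    flush(len(text))
    if not sections:
        sections = [Section(label="unknown", text=text)]
    return sections


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_jsonl(path: Path) -> Iterator[Document]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                doc_id = str(rec["pmid"])
                title = rec.get("title", "")
                if "sections" in rec:
                    title_sents = ([Sentence(title, 0, len(title), 0)]
                                   if title else [])
                    secs = [Section(label="title", text=title,
                                    sentences=title_sents)]
                    for s in rec["sections"]:
                        label = s.get("label", "unknown")
                        if label not in SECTION_LABELS:
                            label = "unknown"
                        secs.append(Section(label=label, text=s.get("text", "")))
                    yield Document(doc_id=doc_id, title=title, sections=secs,
                                   source_kind="fulltext_plain")
                else:
                    yield make_abstract_document(doc_id, title,
                                                 rec.get("abstract", ""))
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                logger.error("line %d of %s: malformed record skipped (%s)",
                             lineno, path, exc)


def _read_pubmed_xml(path: Path) -> Iterator[Document]:
    tree = etree.parse(str(path))
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if not pmid:
            logger.error("PubmedArticle without PMID skipped in %s", path)
            continue
        title = "".join(art.find(".//ArticleTitle").itertext()) \
            if art.find(".//ArticleTitle") is not None else ""
        abst_nodes = art.findall(".//Abstract/AbstractText")
        abstract = " ".join("".join(n.itertext()) for n in abst_nodes).strip()
        if not abstract:
            logger.warning("PMID %s: missing AbstractText, empty abstract", pmid)
        yield make_abstract_document(pmid.strip(), title.strip(), abstract)


def _read_jats_xml(path: Path) -> Iterator[Document]:
    tree = etree.parse(str(path))
    root = tree.getroot()
    articles = root.iter("article") if root.tag != "article" else [root]
    for idx, art in enumerate(articles):
        pmid = (art.findtext(".//article-id[@pub-id-type='pmid']")
                or art.findtext(".//article-id") or f"article{idx + 1}")
        title_el = art.find(".//article-title")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        title_sents = [Sentence(title, 0, len(title), 0)] if title else []
        secs = [Section(label="title", text=title, sentences=title_sents)]
        abst = art.find(".//abstract")
        if abst is not None:
            secs.append(Section(label="abstract",
                                text=" ".join("".join(abst.itertext()).split())))
        for sec in art.iter("sec"):
            head = sec.findtext("title") or ""
            key = head.strip().rstrip(" :.").lower()
            label = HEADING_MAP.get(key, "unknown")
            paras = [" ".join("".join(p.itertext()).split())
                     for p in sec.findall("p")]
            secs.append(Section(label=label, text="\n".join(paras)))
        yield Document(doc_id=str(pmid).strip(), title=title, sections=secs,
                       source_kind="fulltext_xml")


def _read_fulltext_text(path: Path) -> Iterator[Document]:
    text = Path(path).read_text(encoding="utf-8")
    secs = sectionize_plaintext(text)
    yield Document(doc_id=Path(path).stem, title="", sections=secs,
                   source_kind="fulltext_plain")


_READERS = {
    "jsonl": _read_jsonl,
    "pubmed_xml": _read_pubmed_xml,
    "fulltext_xml": _read_jats_xml,
    "fulltext_text": _read_fulltext_text,
}


def read_documents(path: str | Path, format: str) -> List[Document]:
    """Read documents from ``path`` in the named format.

    Malformed individual records are logged and skipped; an unreadable file or
    unknown format raises.
    """
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of "
                         f"{sorted(_READERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return list(_READERS[format](path))


def write_documents_jsonl(docs: Sequence[Document], path: str | Path) -> None:
    """Serialise documents to the canonical JSONL dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            if doc.source_kind == "abstract":
                abstract = next((s.text for s in doc.sections
                                 if s.label == "abstract"), "")
                rec = {"pmid": doc.doc_id, "title": doc.title,
                       "abstract": abstract}
            else:
                rec = {"pmid": doc.doc_id, "title": doc.title,
                       "sections": [{"label": s.label, "text": s.text}
                                    for s in doc.sections
                                    if s.label != "title"]}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
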