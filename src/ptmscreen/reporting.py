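"""Curator-facing output: highlighted HTML screening reports and the
tab-delimited phosphosite validation file.

The HTML report is a single self-contained file, partitioned by PTM class.
Three visually distinct highlight classes are used: extracted sentences
(orange), PTM trigger/site information (yellow), gene/protein mentions
(blue).  All source text is HTML-escaped; contained spans nest, partial
overlaps are resolved by trimming the later span.
"""

from __future__ import annotations

import html
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .corpus_io import Document
from .extraction import PTMEvent
from .gene_mention import GeneMention, RankedGene
from .validation import ValidationHit

DEFAULT_STYLE = """
body { font-family: sans-serif; margin: 2em; max-width: 60em; }
h1 { border-bottom: 2px solid #444; }
h2 { background: #eee; padding: 0.2em 0.5em; }
.doc { border: 1px solid #ccc; margin: 1em 0; padding: 0.5em 1em; }
.sent { background: #ffd9a0; }
.ptm  { background: #ffff66; }
.gene { background: #b3d9ff; }
table { border-collapse: collapse; margin: 0.5em 0; }
td, th { border: 1px solid #999; padding: 0.15em 0.5em; }
"""

#: URL templates are configuration, keeping the artifact network-free.
UNIPROT_URL = "https://www.uniprot.org/uniprotkb/{accession}"
PUBMED_URL = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"


def _render_spans(text: str, spans: List[Tuple[int, int, str]]) -> str:
    """Escape ``text`` and wrap each (start, end, css_class) span.

    Spans are sorted by (start, -length); a span fully contained in the
    previous one nests, a partially overlapping span is trimmed to start
    where the previous one ends.
    """
    cleaned: List[Tuple[int, int, str]] = []
    for start, end, css in sorted(spans, key=lambda s: (s[0], -(s[1] - s[0]))):
        start = max(0, start)
        end = min(len(text), end)
        if start >= end:
            continue
        if cleaned:
            ps, pe, _ = cleaned[-1]
            if start < pe and end > pe:      # partial overlap: trim
                start = pe
            if start >= end:
                continue
        cleaned.append((start, end, css))

    def render(segment_start: int, segment_end: int,
               items: List[Tuple[int, int, str]]) -> str:
        out = []
        pos = segment_start
        i = 0
        while i < len(items):
            s, e, css = items[i]
            out.append(html.escape(text[pos:s]))
            inner = []
            j = i + 1
            while j < len(items) and items[j][1] <= e:
                inner.append(items[j])
                j += 1
            out.append(f'<span class="{css}">'
                       f'{render(s, e, inner)}</span>')
            pos = e
            i = j
        out.append(html.escape(text[pos:segment_end]))
        return "".join(out)

    return render(0, len(text), cleaned)


def render_screening_report(docs: Sequence[Document],
                            events: Sequence[PTMEvent],
                            rankings: Dict[str, List[RankedGene]],
                            out_path: str | Path,
                            mentions: Dict[str, List[GeneMention]] | None = None,
                            min_gene_score: int = 0,
                            ptm_filter: Sequence[str] | None = None) -> None:
    """Write the screening report.

    One block per (PTM class, document); documents with no events are
    omitted.  Output is deterministic given fixed input ordering.
    """
    mentions = mentions or {}
    by_ptm: Dict[str, Dict[str, List[PTMEvent]]] = {}
    for ev in events:
        if ptm_filter and ev.ptm not in ptm_filter:
            continue
        by_ptm.setdefault(ev.ptm, {}).setdefault(ev.doc_id, []).append(ev)
    doc_index = {d.doc_id: d for d in docs}

    parts = [f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
             f"<title>PTM screening report</title>"
             f"<style>{DEFAULT_STYLE}</style></head><body>"
             f"<h1>PTM screening report</h1>"]
    for ptm in sorted(by_ptm):
        parts.append(f"<h2>{html.escape(ptm)}</h2>")
        for doc_id in sorted(by_ptm[ptm], key=lambda d: str(d)):
            doc = doc_index.get(doc_id)
            if doc is None:
                continue
            doc_events = by_ptm[ptm][doc_id]
            doc_mentions = mentions.get(doc_id, [])
            parts.append(f"<div class='doc'><h3>"
                         f"{html.escape(doc_id)}</h3>")
            for section in doc.sections:
                sec_events = [e for e in doc_events
                              if e.section_label == section.label]
                sec_mentions = [m for m in doc_mentions
                                if m.section_label == section.label]
                if not section.text:
                    continue
                spans: List[Tuple[int, int, str]] = []
                for sent in section.sentences:
                    sent_events = [e for e in sec_events
                                   if e.sentence_index == sent.index]
                    if sent_events:
                        spans.append((sent.start, sent.end, "sent"))
                        for ev in sent_events:
                            ts, te = ev.trigger.span
                            spans.append((sent.start + ts, sent.start + te,
                                          "ptm"))
                            for site in ev.sites:
                                spans.append((sent.start + site.span[0],
                                              sent.start + site.span[1],
                                              "ptm"))
                    for m in sec_mentions:
                        if m.sentence_index == sent.index:
                            spans.append((sent.start + m.span[0],
                                          sent.start + m.span[1], "gene"))
                parts.append(f"<p><b>{html.escape(section.label)}:</b> "
                             f"{_render_spans(section.text, spans)}</p>")
            # extracted site list
            site_rows = []
            for ev in doc_events:
                for site in ev.sites:
                    pos = ", ".join(str(p) for p in site.positions) or "–"
                    site_rows.append(f"<tr><td>{html.escape(ev.ptm)}</td>"
                                     f"<td>{html.escape(site.residue)}</td>"
                                     f"<td>{pos}</td></tr>")
            if site_rows:
                parts.append("<table><tr><th>PTM</th><th>residue</th>"
                             "<th>positions</th></tr>"
                             + "".join(site_rows) + "</table>")
            ranking = [g for g in rankings.get(doc_id, [])
                       if g.score >= min_gene_score]
            if ranking:
                rows = "".join(
                    f"<tr><td>{g.rank}</td><td>{html.escape(g.surface)}</td>"
                    f"<td>{g.score}</td></tr>" for g in ranking)
                parts.append("<table><tr><th>rank</th><th>gene/protein</th>"
                             "<th>score</th></tr>" + rows + "</table>")
            parts.append("</div>")
    parts.append("</body></html>")
    Path(out_path).write_text("".join(parts), encoding="utf-8")


VALIDATION_COLUMNS = ["accession", "residue", "position", "matched_position",
                      "offset_applied", "doc_id", "section", "sentence",
                      "entry_url", "abstract_url"]


def write_validation_tsv(hits: Sequence[ValidationHit],
                         out_path: str | Path) -> None:
    """One row per hit, header always present, stable sort by
    (accession, position, doc_id); UniProt and PubMed links are built from
    configurable URL templates."""
    rows = [{
        "accession": h.accession,
        "residue": h.residue,
        "position": h.position,
        "matched_position": h.matched_position,
        "offset_applied": h.offset_applied,
        "doc_id": h.doc_id,
        "section": h.section_label,
        "sentence": h.sentence_text,
        "entry_url": UNIPROT_URL.format(accession=h.accession),
        "abstract_url": PUBMED_URL.format(pmid=h.doc_id),
    } for h in hits]
    df = pd.DataFrame(rows, columns=VALIDATION_COLUMNS)
    if rows:
        df = df.sort_values(["accession", "position", "doc_id"],
                            kind="stable")
    df.to_csv(out_path, sep="\t", index=False)


def read_validation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
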