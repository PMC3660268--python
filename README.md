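# ptmscreen

Rule-based extraction of protein post-translational modification (PTM)
events from biomedical text, built for database-curation triage.

## The problem

Curators who annotate PTMs — phosphorylation, acetylation, glycosylation and
their kin — must find, in an ever-growing literature, the sentences that
state *which* modification occurs, on *which* amino acid, at *which*
sequence position, and on *which* protein. `ptmscreen` automates the triage:
it screens abstracts (or sectioned full text) for the seven PTM classes most
frequently annotated in protein knowledgebases, extracts the modification
statements, ranks candidate modified proteins, and cross-checks extracted
phosphosites against an annotation table of sites known only from
high-throughput proteomics, so that curators can attach supporting
literature to them.

## The method

Extraction is deliberately shallow — pattern matching and rules, no
syntactic parsing — so that millions of abstracts can be processed cheaply:

1. **Triage.** A document is kept for a PTM class iff one of the class's
   *filtering tokens* (`acet`, `amid`, `disulf`, `glyco`, `methyl`,
   `phospho`, `sulf`, plus orthographic variants such as `(di)sulph`)
   occurs anywhere in its text.
2. **Trigger matching.** Each sentence is tested against fine-grained,
   morphology-aware trigger patterns (e.g. `phosphorylat(e|es|ed|ing|ion)`).
   Matches are vetoed by class-specific stop terms that capture chemical
   false friends (O-acetylserine, acetylcholine, sulfanilamide, Sepharose,
   methyl esters) and by context rules (a methylation trigger near DNA/CpG
   cues with no protein residue nearby is discarded).
3. **Site and position.** A sentence is retained only if it also names a
   modifiable residue (spelled out, `Ser-15`, `S21`), a protein terminus, or
   a generic "site"/"residue" term. Sequence positions are recovered by
   preposition-based parsing: from the residue mention, the parser walks an
   unbroken chain of linking elements (prepositions, punctuation,
   conjunctions, digits) and collects every integer it reaches — so
   "serine positions 21, 33, 230, and 237" yields all four coordinates.
   Position extraction is optional except when screening abstracts for
   phosphorylation, where a sentence must carry a position to be retained.
4. **Gene ranking.** Candidate gene/protein mentions (pluggable tagger; a
   built-in orthographic heuristic by default) are scored +1 if present in
   an extracted PTM sentence, +1 if present in the title, +1 if the most
   frequent mention in the document, and ranked.
5. **Phosphosite validation.** Extracted phosphosites are matched against a
   TSV of annotated sites by residue and position, allowing for
   mature-chain numbering offsets (`position − mature_offset`), with
   species filtering and optional protein co-mention requirements.

Outputs are a highlighted HTML screening report (sentences, PTM/site spans,
and gene mentions in three distinct colours, with the ranked protein list)
and a tab-delimited validation file with database and abstract links.

## Worked example

```python
from ptmscreen import (default_lexicon, extract_events,
                       tag_gene_mentions, rank_gene_mentions)
from ptmscreen.corpus_io import make_abstract_document

lex = default_lexicon()
doc = make_abstract_document(
    "22584576", "Phosphorylation of human biliverdin reductase by PKCdelta.",
    "LC-MS/MS analysis of PKCdelta-activated intact hBVR identified "
    "phosphorylated serine positions 21, 33, 230, and 237 as sites of "
    "modification.")
for ev in extract_events(doc, lex, mode="abstract_screen"):
    for site in ev.sites:
        print(ev.ptm, repr(ev.trigger.surface), site.residue, site.positions)
mentions = tag_gene_mentions(doc)
for g in rank_gene_mentions(doc, mentions,
                            extract_events(doc, lex, "abstract_screen")):
    print(f"rank {g.rank}: {g.surface}  score={g.score}")
```

prints

```
phosphorylation 'phosphorylated' serine [21, 33, 230, 237]
rank 1: PKCdelta  score=3
rank 2: hBVR  score=1
```

One phosphorylation event was extracted: the trigger word, the serine site,
and all four sequence positions reached through the linking chain. The gene
ranking puts the kinase first (it appears in the title, in the event
sentence, and most frequently) and the actual substrate second — candidate
ranking is a triage aid, and the ranked list is presented to a curator, not
asserted as the substrate.

## Command line

```sh
ptmscreen make-fixtures --n 1000 --seed 1 --out corpus/   # synthetic corpus
ptmscreen screen --input corpus/docs.jsonl --out report.html
ptmscreen validate-sites --input corpus/docs.jsonl \
    --annotations corpus/annotations.tsv --out validation.tsv
ptmscreen evaluate --input corpus/docs.jsonl --gold corpus/gold.jsonl
```

`make-fixtures` generates a seeded synthetic corpus with planted PTM
statements, trap sentences (chemical names, DNA methylation, enzyme
descriptions, wrong-species homolog statements) and a matching annotation
table, with full ground truth for evaluation.

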