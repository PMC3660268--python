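# Methods

## Scope and model of the text

`ptmscreen` treats a document as an ordered list of labelled sections
(title, abstract, introduction, methods, results, discussion, unknown),
each split into sentences with exact character offsets (0-based, half-open).
Protein sequence positions, by contrast, are 1-based throughout, following
the UniProt convention. Titles are treated as a single atomic sentence:
titles are single statements regardless of internal punctuation, and the
alternative (splitting them) only creates boundary artifacts around
abbreviation-dense title text.

Sentence splitting is rule-based: a boundary is a run of `.?!` followed by
whitespace and an uppercase letter or digit, suppressed after a versioned
list of biomedical abbreviations (`Fig.`, `et al.`, `e.g.`, three-letter
residue codes, single-capital initials, …) and inside unclosed
parentheses/brackets. A transparent, testable list was preferred over an
opaque statistical splitter; the abbreviation list is part of the package
surface and extending it is a data change, not a code change.

## The extraction cascade

**Triage** is an unanchored, case-insensitive substring test: `phospho`
matches `phosphoproteome`, `hyperphosphorylation`, `phosphosite`. This is
deliberately recall-heavy — triage only decides whether the per-sentence
machinery runs, and a missed token here is unrecoverable downstream. For
full-text input the test is applied per section.

**Trigger patterns** are word-boundary-aware regular expressions with
morphological suffix alternation (`(de|hyper|auto…)?phosphorylat(e|es|ed|
ing|ion|ions)`), compiled case-insensitively. Every pattern must embed its
class's filtering token in its literal core — this invariant is validated
at lexicon load and guarantees triage soundness (no sentence-level match
that triage could not have seen). Acetylation triggers include
`N-/O-acetyl-<residue>` compound forms because genuine products
(N-acetylmethionine) share this shape with chemical false friends; the
false friends are then handled by stop terms rather than by narrowing the
pattern, which keeps recall for the genuine forms.

**Stop terms** veto a trigger when they occur overlapping or within 15
characters of the trigger span. The window approximates "in apposition to"
without parsing: large enough to catch `…acetylation (O-acetylserine)…`
style appositives, small enough not to suppress a genuine trigger elsewhere
in a long sentence. The **DNA-methylation rule** is a context rule rather
than a stop term: a methylation trigger is vetoed when a cue (`DNA`, `CpG`,
`cytosine`, `promoter methylation`, `histone-free`) occurs in the sentence
and no modifiable protein residue mention lies closer to the trigger than
the nearest cue. The distance comparison keeps sentences like "histone H3
lysine 9 methylation alters DNA repair", where the residue sits next to the
trigger and the cue is incidental.

**Site mentions** accept spelled-out residue names (optionally with an
attached hyphen-number: `serine-21`), capitalised three-letter codes with
optional phospho prefix and compact position (`Ser`, `Ser-15`, `pSer21`) —
capitalisation is required so the pronoun "his" and the verb "met" are
never residue mentions — and one-letter codes only when immediately
followed by digits (`S21`; a bare `S` is never a mention). Terminus
expressions (`N-terminal`, `carboxy-terminus`) count as sites for the
classes that modify protein extremities (acetylation, methylation,
amidation). Generic `site`/`residue` mentions are used only when no
concrete residue mention exists in the sentence. No syntactic dependency
between trigger and site is required; the cost of this choice is a known
class of co-mention false positives (a title naming both
"cysteine-containing" and "disulfide-bonded" yields a disulfide event),
which is accepted behaviour and pinned by a regression test.

**Position parsing** walks rightward from the residue mention through an
unbroken chain of linking elements — the lexicon's linking terms
(`position(s)`, `residue(s)`, `site(s)`, `at`, `on`, `in`, `of`, `the`,
`and`, `or`), commas, semicolons, slashes, hyphens, parentheses and digits
— collecting every integer until the first non-linking token. The mirrored
leftward scan ("position 21 of the serine residue") additionally requires
that the chain be introduced by a positional noun, so bare counts ("all 5
serine residues") are not misread as coordinates; the rightward scan does
not need this guard because residue-then-number is the conventional order.
Numeric ranges (`Ser 21-33`) contribute their endpoints only — range
expansion semantics are ambiguous for PTM sites — with a logged warning.
Position 0 and integers above 99,999 are skipped with a warning.
Duplicates collapse in first-occurrence order. The grammar is verified
against an independently written brute-force chain scanner on randomly
generated linking-chain sentences (10,000 cases in the acceptance suite).

**Mode semantics.** In `abstract_screen` mode, classes flagged
`position_required_in_abstract_screen` (phosphorylation in the default
lexicon) keep only sentences with at least one extracted position —
phosphorylation is mentioned so pervasively that position-free abstracts
are mostly uninformative for site curation. `unrestricted` mode lifts the
requirement; `fulltext` mode screens each section independently and labels
events with their section. The flag is a lexicon property and a CLI
override because the screening and citation-completion workflows need
different settings.

## Gene mention ranking

The tagger is a contract (text in, spans out): any external tagger can be
plugged in directly or via a tab-separated span-exchange file. The built-in
heuristic tags tokens with gene-name orthography — all-caps symbols of
length 2–6 and tokens mixing case or letters/digits with an internal
capital or digit — behind a small blocklist (DNA, RNA, ATP, …) and an
exclusion for residue-style tokens (`S21`). Surface forms are grouped by
case-insensitive equality only; normalisation to database identifiers is
out of scope. The score is the sum of three binary components (event
sentence, title, most frequent). All forms tied at maximal frequency
receive the frequency point — any other tie rule would be arbitrary — and
score ties are broken by earliest first mention in document order, making
the ranking invariant under permutation of the tagger's output.

## Phosphosite validation

Annotated sites arrive as a TSV (accession, names, species, one-letter
residue, canonical position, mature offset, evidence label). Literature
retrieval is expressed as a declarative query descriptor per protein:
names OR-joined, a species conjunct for non-human proteins, a synonym
fallback tier used only when the primary names retrieve nothing, and a
20,000-document cap with individually over-broad names dropped as
non-specific. Descriptors are executed against a local corpus; no network
client is included. The species filter is asymmetric by design: non-human
queries are already species-constrained, while human-protein retrievals
drop any document mentioning another species (word-boundary match against
a species-name lexicon with common synonyms such as murine/Mus musculus).

A site match requires residue compatibility (generic "site" mentions match
any residue; a flag disables this) and position equality against either the
canonical position or `position − mature_offset`, the latter flagged in the
output. The single-integer offset captures signal-peptide/propeptide
processing; full isoform coordinate mapping is out of scope. With
co-mention required, the event sentence must contain an annotation name or
an automatically generated morphological variant (case, hyphen/space,
plural, Greek-letter spelling). Homolog misattribution — a conserved site
reported in a closely related species' protein — is not algorithmically
solvable at this level; hits carry the matched name so curators can audit.

## Evaluation

Abstract-level scoring counts a retrieved positive as tp, a retrieved
negative as fp, and a missed positive as fn **only if** the site
information was present in the abstract; missed positives whose information
lives only in the full text are *exempted* and appear in no count. The
exemption matters because gold labels inherited from full-text curation
systematically overstate what an abstract screen could ever recover.
Event-level scoring matches greedily, one-to-one, within a document, under
either `trigger+residue` or `trigger+residue+positions`; the strict policy
uses exact position-set equality — partial credit is not given, which is
conservative and unambiguous.

## Synthetic data

The generator assembles abstracts from packaged sentence templates: planted
positives covering every branch of the linking grammar (single position,
enumeration, compact three-/one-letter forms, leftward linking, terminus
and generic-site mentions), trap sentences instantiating the documented
false-positive classes (chemical names, DNA/CpG methylation, enzyme
descriptions without site mentions, homolog statements in murine context),
neutral filler, and positives whose site information is withheld from the
abstract (exercising the exemption rule). Gold labels are derived from the
templates actually sampled, never by running the extractor, so ground truth
is independent of the system under test. Default rates: 8% positives per
class (56% in total), 18% traps, 4% abstract-negative positives, remainder
filler — a deliberately information-dense mixture so that a 1,000-document
corpus exercises every rule branch; real PubMed streams are far sparser.
Each document carries a unique main gene plus one distractor mention, so
annotation rows map one-to-one onto supporting documents and ranking
behaviour is measurable. 60% of positioned phosphorylation positives
receive an annotation row; 30% of those carry a non-zero mature offset (18,
24 or 30 residues); 20% are assigned to yeast to exercise the
species-conjunct path. A single seeded PRNG determines the corpus; the seed
is recorded in `manifest.json`.

What passing on this corpus shows: the rule mechanics — triage soundness,
the veto rules, the position grammar, offset arithmetic, the species and
co-mention filters — behave exactly as specified. What it does not show:
performance on real prose, whose phrasing diversity, negation, and
ambiguity the templates deliberately do not model; precision/recall of 1.0
on the synthetic corpus is a correctness check, not a performance claim.

## Numerical and degenerate-input choices

Empty text yields empty sentence lists, empty event lists, and header-only
output files, never errors. Malformed corpus records are skipped with a
logged doc identifier; an unreadable file is fatal. Overlapping trigger
matches of one class merge to the widest span; overlapping residue matches
resolve leftmost-longest. HTML rendering escapes all source text and
resolves span overlaps by nesting contained spans and trimming partial
overlaps. All pipelines are deterministic: identical inputs and
configuration produce byte-identical reports, event files, and TSVs.

## Known limitations

- No negation or speculation handling; "was not phosphorylated" is
  extracted.
- No trigger–site dependency checking (see the disulfide title example).
- Enzyme-description sentences that name both a modification and a residue
  (e.g. a transferase described with its acceptor residue) are extracted;
  filtering them needs syntax or semantics the design excludes.
- The catalysing enzyme and disulfide partner pairing are not extracted.
- Gene mentions are not normalised to database identifiers, and species
  assignment of individual mentions is not attempted.
- The default lexicon is a documented reconstruction adequate for the
  packaged examples and tests; curators are expected to extend it in
  production use.
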