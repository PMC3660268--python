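"""Synthetic corpus generation with known ground truth.

Documents are assembled from packaged sentence templates: planted positive
PTM statements (covering every branch of the position-linking grammar:
single position, enumeration, compact Ser-21/S21 forms, terminus mentions,
generic "site" mentions, leftward linking), trap sentences instantiating the
documented false-positive classes (chemical names such as O-acetylserine,
DNA/CpG methylation, enzyme descriptions, homolog/wrong-species statements),
neutral filler, and positives whose site information is withheld from the
abstract (exemption cases).  Gold labels are computed from the templates
actually sampled, never by running the extractor, so the ground truth is
independent of the system under test.

Every gene name is unique to its document, so the annotation table rows map
one-to-one onto the documents that support them.  A single seeded PRNG fully
determines the output; the seed is recorded in the manifest.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .corpus_io import Document, make_abstract_document, write_documents_jsonl
from .evaluation import GoldEvent, GoldLabel
from .lexicon import KNOWN_PTM_CLASSES
from .residues import FULL_TO_ONE, FULL_TO_THREE
from .validation import SiteAnnotation

#: residues sampled when a template does not pin one
SAMPLED_RESIDUES = {
    "phosphorylation": ["serine", "threonine", "tyrosine"],
    "methylation": ["lysine", "arginine"],
}

GENE_PREFIXES = ["TK", "ST", "MB", "RP", "NL", "PD", "YT", "KR", "SG", "HQ"]
DISTRACTOR_PREFIXES = ["XD", "ZN", "UB", "GP", "QV"]


@dataclass
class FixtureSpec:
    n_documents: int = 100
    seed: int = 0
    #: per-PTM probability that a document is a planted positive
    ptm_rates: Dict[str, float] = field(default_factory=lambda: {
        ptm: 0.08 for ptm in sorted(KNOWN_PTM_CLASSES)})
    #: per-trap-class probability
    trap_rates: Dict[str, float] = field(default_factory=lambda: {
        "chemical_name": 0.05, "dna_methylation": 0.04,
        "enzyme_description": 0.05, "homolog_species": 0.04})
    #: probability of a positive whose site info is withheld from the abstract
    fulltext_only_rate: float = 0.04
    #: fraction of phosphorylation positives that get an annotation-table row
    annotation_fraction: float = 0.6
    #: fraction of annotated sites carrying a non-zero mature offset
    mature_offset_fraction: float = 0.3
    #: fraction of annotated sites assigned a non-human (yeast) species
    nonhuman_fraction: float = 0.2

    def validate(self) -> None:
        rates = (list(self.ptm_rates.values()) + list(self.trap_rates.values())
                 + [self.fulltext_only_rate, self.annotation_fraction,
                    self.mature_offset_fraction, self.nonhuman_fraction])
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        total = sum(self.ptm_rates.values()) + sum(self.trap_rates.values()) \
            + self.fulltext_only_rate
        if total > 1:
            raise ValueError(f"category rates sum to {total:.2f} > 1")


@dataclass
class ExpectedHit:
    accession: str
    residue: str       # one-letter
    position: int      # canonical (annotation) position
    matched_position: int
    offset_applied: bool
    doc_id: str


@dataclass
class SyntheticCorpus:
    documents: List[Document]
    gold: List[GoldLabel]
    annotations: List[SiteAnnotation]
    expected_hits: List[ExpectedHit]
    spec: FixtureSpec


def _load_table(name: str) -> List[List[str]]:
    text = (resources.files("ptmscreen") / "data" / "templates" /
            name).read_text(encoding="utf-8")
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("|"))
    return rows


def _fill(template: str, gene: str, residue: Optional[str],
          positions: List[int]) -> str:
    text = template.replace("{gene}", gene)
    if residue:
        text = text.replace("{residue}", residue)
        text = text.replace("{Residue3}", FULL_TO_THREE[residue])
        text = text.replace("{R1}", FULL_TO_ONE[residue])
    if positions:
        text = text.replace("{pos}", str(positions[0]))
        if len(positions) > 1:
            text = text.replace("{pos2}", str(positions[1]))
        if "{poslist}" in text:
            head = ", ".join(str(p) for p in positions[:-1])
            text = text.replace("{poslist}", f"{head} and {positions[-1]}"
                                if len(positions) > 1 else str(positions[0]))
    return text


def _positions_for_style(style: str, rng: random.Random) -> List[int]:
    if style in ("none", "terminus"):
        return []
    if style == "enumeration":
        k = rng.randint(3, 4)
    elif style == "pair":
        k = 2
    else:
        k = 1
    return sorted(rng.sample(range(5, 400), k))


def generate_synthetic_corpus(spec: FixtureSpec,
                              out_dir: Optional[str | Path] = None
                              ) -> SyntheticCorpus:
    """Generate the corpus; optionally write docs.jsonl, gold.jsonl,
    annotations.tsv and manifest.json under ``out_dir``."""
    spec.validate()
    rng = random.Random(spec.seed)
    positives = _load_table("positives.txt")
    traps = _load_table("traps.txt")
    homolog_templates = [r[0] for r in _load_table("homolog.txt")]
    ft_only = _load_table("fulltext_only.txt")
    filler = [r[0] for r in _load_table("filler.txt")]
    if not filler:
        raise ValueError("empty filler template list")

    # category thresholds for a single uniform draw per document
    categories: List[Tuple[str, str, float]] = []  # (kind, key, cumulative)
    acc = 0.0
    for ptm, rate in sorted(spec.ptm_rates.items()):
        acc += rate
        categories.append(("positive", ptm, acc))
    for trap, rate in sorted(spec.trap_rates.items()):
        acc += rate
        categories.append(("trap", trap, acc))
    acc += spec.fulltext_only_rate
    categories.append(("fulltext_only", "", acc))

    documents: List[Document] = []
    gold: List[GoldLabel] = []
    annotations: List[SiteAnnotation] = []
    expected_hits: List[ExpectedHit] = []
    # deferred homolog traps need an existing annotation to collide with
    deferred_homologs: List[str] = []

    def unique_gene(i: int, distractor: bool = False) -> str:
        prefixes = DISTRACTOR_PREFIXES if distractor else GENE_PREFIXES
        return f"{rng.choice(prefixes)}{i + 1}"

    def labels_for(doc_id: str, positive_ptm: Optional[str],
                   info_in_abstract: bool = True,
                   events: Optional[List[GoldEvent]] = None) -> None:
        for ptm in sorted(KNOWN_PTM_CLASSES):
            if ptm == positive_ptm:
                gold.append(GoldLabel(doc_id=doc_id, ptm=ptm,
                                      label="positive",
                                      info_in_abstract=info_in_abstract,
                                      events=events or []))
            else:
                gold.append(GoldLabel(doc_id=doc_id, ptm=ptm,
                                      label="negative"))

    def assemble(doc_id: str, gene: str, payload: str,
                 extra: Optional[str] = None) -> Document:
        title = f"Characterization of {gene} in cellular signaling."
        # exactly one distractor gene mention per document
        distractor = unique_gene(int(doc_id) + 5000, distractor=True)
        sents = [rng.choice(filler), payload,
                 f"Co-purification with {distractor} was also observed."]
        if extra:
            sents.append(extra)
        return make_abstract_document(doc_id, title, " ".join(sents))

    for i in range(spec.n_documents):
        doc_id = str(i + 1)
        gene = unique_gene(i)
        draw = rng.random()
        kind, key = "filler", ""
        for k, ky, cum in categories:
            if draw < cum:
                kind, key = k, ky
                break

        if kind == "positive":
            ptm = key
            ptm_templates = [r for r in positives if r[0] == ptm]
            _, style, residue_spec, template = rng.choice(ptm_templates)
            residue = (residue_spec if residue_spec != "-" else
                       rng.choice(SAMPLED_RESIDUES[ptm]))
            positions = _positions_for_style(style, rng)
            payload = _fill(template, gene, residue, positions)
            extra = None
            annotated = (ptm == "phosphorylation" and positions
                         and rng.random() < spec.annotation_fraction)
            if annotated:
                offset = (rng.choice([18, 24, 30])
                          if rng.random() < spec.mature_offset_fraction else 0)
                stated = positions[0]
                species = "human"
                if rng.random() < spec.nonhuman_fraction:
                    species = "Saccharomyces cerevisiae"
                    extra = ("All experiments were performed in "
                             "Saccharomyces cerevisiae.")
                accession = f"P{10000 + i}"
                annotations.append(SiteAnnotation(
                    accession=accession, names=[gene], species=species,
                    residue=FULL_TO_ONE[residue], position=stated + offset,
                    mature_offset=offset,
                    evidence="PHOSPHORYLATION [LARGE SCALE ANALYSIS]"))
                expected_hits.append(ExpectedHit(
                    accession=accession, residue=FULL_TO_ONE[residue],
                    position=stated + offset, matched_position=stated,
                    offset_applied=offset > 0, doc_id=doc_id))
            documents.append(assemble(doc_id, gene, payload, extra))
            gold_residue = "generic" if style == "generic" else residue
            labels_for(doc_id, ptm, events=[GoldEvent(
                ptm=ptm, residue=gold_residue, positions=positions)])

        elif kind == "trap" and key == "homolog_species":
            deferred_homologs.append(doc_id)
            # placeholder; filled after annotations exist
            documents.append(None)  # type: ignore[arg-type]

        elif kind == "trap":
            trap_templates = [r for r in traps if r[0] == key]
            _, ptm, template = rng.choice(trap_templates)
            payload = template.replace("{gene}", gene)
            documents.append(assemble(doc_id, gene, payload))
            labels_for(doc_id, None)

        elif kind == "fulltext_only":
            ptm, template = rng.choice(ft_only)
            payload = template.replace("{gene}", gene)
            documents.append(assemble(doc_id, gene, payload))
            labels_for(doc_id, ptm, info_in_abstract=False)

        else:
            documents.append(assemble(doc_id, gene,
                                      rng.choice(filler)))
            labels_for(doc_id, None)

    # homolog traps: restate an annotated human site in a murine context
    human_annotations = [a for a in annotations if a.species == "human"]
    for doc_id in deferred_homologs:
        idx = int(doc_id) - 1
        if not human_annotations:
            # no annotation to collide with: degrade to a filler document
            documents[idx] = assemble(doc_id, unique_gene(idx),
                                      rng.choice(filler))
            labels_for(doc_id, None)
            continue
        ann = rng.choice(human_annotations)
        residue_full = {v: k for k, v in FULL_TO_ONE.items()}[ann.residue]
        stated = ann.position - ann.mature_offset
        template = rng.choice(homolog_templates)
        payload = (template.replace("{gene}", ann.names[0])
                   .replace("{residue}", residue_full)
                   .replace("{pos}", str(stated)))
        title = (f"Regulation of {ann.names[0]} in murine development.")
        sents = [rng.choice(filler), payload, rng.choice(filler)]
        documents[idx] = make_abstract_document(doc_id, title,
                                                " ".join(sents))
        labels_for(doc_id, "phosphorylation", events=[GoldEvent(
            ptm="phosphorylation", residue=residue_full,
            positions=[stated])])

    gold.sort(key=lambda g: (int(g.doc_id), g.ptm))

    corpus = SyntheticCorpus(documents=documents, gold=gold,
                             annotations=annotations,
                             expected_hits=expected_hits, spec=spec)
    if out_dir is not None:
        write_corpus(corpus, out_dir)
    return corpus


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_documents_jsonl(corpus.documents, out / "docs.jsonl")
    with open(out / "gold.jsonl", "w", encoding="utf-8") as fh:
        for g in corpus.gold:
            rec = {"doc_id": g.doc_id, "ptm": g.ptm, "label": g.label}
            if g.label == "positive":
                rec["info_in_abstract"] = g.info_in_abstract
                rec["events"] = [{"ptm": e.ptm, "residue": e.residue,
                                  "positions": e.positions}
                                 for e in g.events]
            fh.write(json.dumps(rec) + "\n")
    with open(out / "annotations.tsv", "w", encoding="utf-8") as fh:
        fh.write("accession\tnames\tspecies\tresidue\tposition\t"
                 "mature_offset\tevidence\n")
        for a in corpus.annotations:
            fh.write(f"{a.accession}\t{';'.join(a.names)}\t{a.species}\t"
                     f"{a.residue}\t{a.position}\t{a.mature_offset}\t"
                     f"{a.evidence}\n")
    manifest = {"seed": corpus.spec.seed,
                "n_documents": corpus.spec.n_documents,
                "ptm_rates": corpus.spec.ptm_rates,
                "trap_rates": corpus.spec.trap_rates,
                "fulltext_only_rate": corpus.spec.fulltext_only_rate}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n",
                                       encoding="utf-8")
    with open(out / "expected_hits.tsv", "w", encoding="utf-8") as fh:
        fh.write("accession\tresidue\tposition\tmatched_position\t"
                 "offset_applied\tdoc_id\n")
        for h in corpus.expected_hits:
            fh.write(f"{h.accession}\t{h.residue}\t{h.position}\t"
                     f"{h.matched_position}\t{h.offset_applied}\t"
                     f"{h.doc_id}\n")
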