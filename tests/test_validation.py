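import pytest

from conftest import abstract
from ptmscreen.extraction import PTMEvent, SiteMention, TriggerMatch
from ptmscreen.validation import (SiteAnnotation, build_protein_query,
                                  execute_query_local, load_site_annotations,
                                  match_events_to_annotations,
                                  morphological_variants,
                                  species_exclusion_filter)


def make_event(positions, residue="serine", sentence="hBVR is "
               "phosphorylated at serine 21 and 33.", doc_id="1"):
    return PTMEvent(
        doc_id=doc_id, section_label="abstract", sentence_index=0,
        sentence_text=sentence, ptm="phosphorylation",
        trigger=TriggerMatch(ptm="phosphorylation", span=(8, 22),
                             surface="phosphorylated"),
        sites=[SiteMention(residue=residue, span=(0, 4),
                           positions=list(positions))])


class TestLoadAnnotations:
    HEADER = ("accession\tnames\tspecies\tresidue\tposition\t"
              "mature_offset\tevidence\n")

    def _load(self, tmp_path, rows):
        p = tmp_path / "ann.tsv"
        p.write_text(self.HEADER + "".join(r + "\n" for r in rows))
        return load_site_annotations(p)

    def test_basic_row(self, tmp_path):
        anns = self._load(tmp_path, [
            "P1\thBVR;BLVRA\thuman\tS\t21\t0\t"
            "PHOSPHORYLATION [LARGE SCALE ANALYSIS]"])
        assert len(anns) == 1
        assert anns[0].names == ["hBVR", "BLVRA"]
        assert anns[0].residue == "S" and anns[0].position == 21

    def test_bad_rows_rejected(self, tmp_path):
        anns = self._load(tmp_path, [
            "P1\tA\thuman\tS\t0\t0\tx",      # position 0
            "P2\tB\thuman\tZ\t5\t0\tx",      # bad residue
            "P3\tC\thuman\tT\t9\t0\tx"])     # good
        assert [a.accession for a in anns] == ["P3"]

    def test_duplicates_collapse(self, tmp_path):
        anns = self._load(tmp_path, [
            "P1\tA\thuman\tS\t21\t0\tx",
            "P1\tA\thuman\tS\t21\t0\tx"])
        assert len(anns) == 1


class TestQueryDescriptor:
    def test_non_human_gets_species_conjunct(self):
        d = build_protein_query({"CDC28"}, "Saccharomyces cerevisiae")
        assert d.species_conjunct == "Saccharomyces cerevisiae"
        assert d.species_postfilter is False

    def test_human_gets_postfilter_instead(self):
        d = build_protein_query({"BLVRA"}, "human")
        assert d.species_conjunct is None
        assert d.species_postfilter is True

    def test_empty_names_error(self):
        with pytest.raises(ValueError):
            build_protein_query([], "human")

    def test_synonym_fallback_tier(self):
        d = build_protein_query(["BLVRA"], "human",
                                synonym_table={"BLVRA": ["hBVR"]})
        assert d.synonym_fallback == ["hBVR"]

    def test_overbroad_term_dropped(self, caplog):
        docs = [abstract(str(i), "T", "the protein binds partners")
                for i in range(5)]
        d = build_protein_query(["protein"], "human", cap=3)
        assert execute_query_local(d, docs) == []

    def test_fallback_used_when_primary_empty(self):
        docs = [abstract("1", "T", "hBVR was studied in detail.")]
        d = build_protein_query(["BLVRA"], "human",
                                synonym_table={"BLVRA": ["hBVR"]})
        assert [x.doc_id for x in execute_query_local(d, docs)] == ["1"]


class TestSpeciesFilter:
    LEXICON = {"human": ["Homo sapiens"], "mouse": ["murine", "Mus musculus"],
               "rat": []}

    def test_other_species_mention_drops(self):
        doc = abstract("1", "T", "Results in murine fibroblasts differed.")
        assert species_exclusion_filter(doc, "human", self.LEXICON) is False

    def test_human_only_mentions_keep(self):
        doc = abstract("1", "T", "Samples from human patients were used.")
        assert species_exclusion_filter(doc, "human", self.LEXICON) is True

    def test_bypassed_for_non_human_target(self):
        doc = abstract("1", "T", "Results in murine fibroblasts differed.")
        assert species_exclusion_filter(doc, "mouse", self.LEXICON) is True


class TestMatching:
    def test_direct_position_match_with_co_mention(self):
        ann = SiteAnnotation(accession="P1", names=["hBVR"], species="human",
                             residue="S", position=21)
        hits = match_events_to_annotations(
            [make_event([21, 33])], [ann], require_co_mention=True)
        assert len(hits) == 1
        assert hits[0].matched_position == 21
        assert hits[0].offset_applied is False

    def test_mature_offset_arithmetic(self):
        ann = SiteAnnotation(accession="P2", names=["hBVR"], species="human",
                             residue="S", position=45, mature_offset=24)
        hits = match_events_to_annotations([make_event([21])], [ann])
        assert len(hits) == 1
        assert hits[0].offset_applied is True
        assert hits[0].matched_position == 21

    def test_residue_mismatch_no_hit(self):
        ann = SiteAnnotation(accession="P1", names=["hBVR"], species="human",
                             residue="T", position=21)
        assert match_events_to_annotations([make_event([21])], [ann]) == []

    def test_generic_site_matches_any_residue_unless_disabled(self):
        ann = SiteAnnotation(accession="P1", names=["hBVR"], species="human",
                             residue="T", position=21)
        ev = make_event([21], residue="generic")
        assert len(match_events_to_annotations([ev], [ann])) == 1
        assert match_events_to_annotations([ev], [ann],
                                           allow_generic=False) == []

    def test_zero_offset_yields_single_hit_per_position(self):
        # with offset 0 the two match conditions coincide: no double count
        ann = SiteAnnotation(accession="P1", names=["hBVR"], species="human",
                             residue="S", position=21, mature_offset=0)
        hits = match_events_to_annotations([make_event([21])], [ann])
        assert len(hits) == 1

    def test_co_mention_monotonicity(self):
        ann = SiteAnnotation(accession="P1", names=["ZZX9"], species="human",
                             residue="S", position=21)
        events = [make_event([21])]   # sentence mentions hBVR, not ZZX9
        free = match_events_to_annotations(events, [ann])
        strict = match_events_to_annotations(events, [ann],
                                             require_co_mention=True)
        assert len(strict) <= len(free)
        assert strict == []

    def test_removing_annotation_removes_its_hits(self):
        anns = [SiteAnnotation(accession="P1", names=["hBVR"],
                               species="human", residue="S", position=21),
                SiteAnnotation(accession="P2", names=["hBVR"],
                               species="human", residue="S", position=33)]
        both = match_events_to_annotations([make_event([21, 33])], anns)
        one = match_events_to_annotations([make_event([21, 33])], anns[:1])
        assert {h.accession for h in both} == {"P1", "P2"}
        assert {h.accession for h in one} == {"P1"}


class TestMorphologicalVariants:
    def test_case_hyphen_plural_greek(self):
        v = morphological_variants("PKC-alpha")
        assert "pkc alpha" in v
        assert "pkcalpha" in v
        assert "pkc-alphas" in v
        assert "pkc-α" in v
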