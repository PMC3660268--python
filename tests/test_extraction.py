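import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import abstract, oracle_rightward, random_chain_sentence, \
    sentence
from ptmscreen.extraction import (SiteMention, detect_site_mentions,
                                  extract_events, match_ptm_sentence,
                                  parse_positions, triage_document)

WORKED_SENTENCE = ("LC-MS/MS analysis of PKCdelta-activated intact hBVR "
                   "identified phosphorylated serine positions 21, 33, 230, "
                   "and 237 as sites of modification.")


class TestTriage:
    @pytest.mark.parametrize("text,expected", [
        ("Tau hyperphosphorylation drives aggregation.", {"phosphorylation"}),
        ("A disulphide bridge stabilizes the fold.", {"disulfide_bond",
                                                      "sulfation"}),
        ("The chaperone assists folding of nascent chains.", set()),
    ])
    def test_token_screen(self, lex, text, expected):
        doc = abstract("1", "", text)
        assert triage_document(doc, lex) == expected

    def test_triage_soundness(self, lex, small_corpus):
        """Every extracted event's class passed triage for its document."""
        for doc in small_corpus.documents:
            triaged = triage_document(doc, lex)
            for ev in extract_events(doc, lex, mode="unrestricted"):
                assert ev.ptm in triaged


class TestTriggerMatching:
    def test_stop_term_vetoes_chemical_name(self, lex):
        s = sentence("Biosynthesis requires O-acetylserine as an intermediate.")
        assert match_ptm_sentence(s, lex.classes["acetylation"], lex) == []

    def test_dna_methylation_excluded(self, lex):
        s = sentence("DNA methylation of CpG islands was profiled.")
        assert match_ptm_sentence(s, lex.classes["methylation"], lex) == []

    def test_protein_methylation_near_residue_survives_dna_cue(self, lex):
        s = sentence("Histone H3 lysine 9 methylation alters DNA repair.")
        matches = match_ptm_sentence(s, lex.classes["methylation"], lex)
        assert len(matches) == 1

    def test_histone_acetylation_trigger(self, lex):
        s = sentence("Lysine 9 acetylation of histone H3 increased.")
        matches = match_ptm_sentence(s, lex.classes["acetylation"], lex)
        assert [m.surface for m in matches] == ["acetylation"]

    def test_matching_is_case_insensitive(self, lex):
        s = sentence("HYPERPHOSPHORYLATION of tau at Ser-202 was seen.")
        assert match_ptm_sentence(s, lex.classes["phosphorylation"], lex)

    def test_adding_stop_term_never_adds_events(self, lex, small_corpus):
        """Monotonicity: a new stop term can only remove events."""
        import copy
        stricter = copy.deepcopy(lex)
        stricter.classes["phosphorylation"].stop_terms.append("kinase")
        for doc in small_corpus.documents[:60]:
            base = extract_events(doc, lex, mode="unrestricted")
            fewer = extract_events(doc, stricter, mode="unrestricted")
            assert len(fewer) <= len(base)


class TestSiteDetection:
    def test_spelled_residue(self, lex):
        s = sentence("OST transfers glycan to asparagine in the "
                     "N-glycosylation sequon.")
        sites = detect_site_mentions(s, lex.classes["glycosylation"], lex)
        assert [m.residue for m in sites] == ["asparagine"]

    def test_no_site_no_mentions(self, lex):
        s = sentence("Phosphorylation increases its activity.")
        assert detect_site_mentions(
            s, lex.classes["phosphorylation"], lex) == []

    def test_terminus_and_residue(self, lex):
        s = sentence("The N-terminal methionine is acetylated.")
        sites = detect_site_mentions(s, lex.classes["acetylation"], lex)
        assert {m.residue for m in sites} == {"N-terminus", "methionine"}

    @pytest.mark.parametrize("text,residue,positions", [
        ("phosphorylated on Ser-15 today", "serine", [15]),
        ("the S21 mutant lost the site", "serine", [21]),
        ("pSer21 antibodies were raised", "serine", [21]),
        ("phosphotyrosine Tyr705 signaling", "tyrosine", [705]),
    ])
    def test_compact_forms(self, lex, text, residue, positions):
        s = sentence(text)
        sites = detect_site_mentions(s, lex.classes["phosphorylation"], lex)
        matching = [m for m in sites if m.residue == residue]
        assert matching and matching[0].positions == positions

    def test_bare_one_letter_is_not_a_mention(self, lex):
        s = sentence("Fraction S was phosphorylated heavily.")
        sites = detect_site_mentions(s, lex.classes["phosphorylation"], lex)
        assert all(m.residue == "generic" for m in sites) or sites == []

    def test_generic_site_only_without_residue(self, lex):
        s = sentence("The major site was phosphorylated.")
        sites = detect_site_mentions(s, lex.classes["phosphorylation"], lex)
        assert [m.residue for m in sites] == ["generic"]


class TestPositionParsing:
    def _parse(self, lex, text, mention):
        start = text.index(mention)
        site = SiteMention(residue="serine",
                           span=(start, start + len(mention)))
        return parse_positions(text, site, lex).positions

    def test_enumeration(self, lex):
        text = ("We identified phosphorylated serine positions 21, 33, 230, "
                "and 237 in the protein.")
        assert self._parse(lex, text, "serine") == [21, 33, 230, 237]

    def test_single_linked_position(self, lex):
        assert self._parse(lex, "phosphorylated at serine 15 here",
                           "serine") == [15]

    def test_no_digits_in_chain(self, lex):
        assert self._parse(lex, "the serine residue was modified",
                           "serine") == []

    def test_chain_stops_at_non_linking_token(self, lex):
        text = "serine kinase assay used 33 cycles"
        assert self._parse(lex, text, "serine") == []

    def test_leftward_linking(self, lex):
        text = "modification at position 21 of the serine residue occurred"
        assert self._parse(lex, text, "serine") == [21]

    def test_leftward_requires_positional_noun(self, lex):
        # a bare count before the mention is not a coordinate
        text = "all 5 serine residues were phosphorylated"
        assert self._parse(lex, text, "serine") == []

    def test_range_contributes_endpoints_only(self, lex):
        assert self._parse(lex, "phosphorylated at serine 21-33 region",
                           "serine") == [21, 33]

    def test_duplicates_collapse_in_first_seen_order(self, lex):
        assert self._parse(lex, "serine positions 33, 21 and 33", "serine") \
            == [33, 21]

    def test_zero_position_skipped(self, lex):
        assert self._parse(lex, "serine at positions 0 and 21", "serine") \
            == [21]

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=300, deadline=None)
    def test_grammar_matches_bruteforce_oracle(self, lex, case_seed):
        """parse_positions agrees with an independently written chain
        scanner on randomly generated linking-chain sentences."""
        rng = random.Random(case_seed)
        text, span, _ = random_chain_sentence(rng, lex.linking_terms)
        site = SiteMention(residue="serine", span=span)
        got = parse_positions(text, site, lex).positions
        assert got == oracle_rightward(text, span[1], lex.linking_terms)


class TestExtractEvents:
    def test_worked_phosphorylation_sentence(self, lex):
        doc = abstract("22584576", "hBVR phosphorylation.", WORKED_SENTENCE)
        events = [e for e in extract_events(doc, lex, mode="abstract_screen")
                  if e.section_label == "abstract"]
        assert len(events) == 1
        (ev,) = events
        assert ev.ptm == "phosphorylation"
        serine = [s for s in ev.sites if s.residue == "serine"]
        assert serine[0].positions == [21, 33, 230, 237]

    def test_position_required_rule_is_mode_dependent(self, lex):
        doc = abstract("1", "", "Tyrosine phosphorylation of STAT3 was "
                                "observed.")
        assert extract_events(doc, lex, mode="abstract_screen") == []
        unrestricted = extract_events(doc, lex, mode="unrestricted")
        assert len(unrestricted) == 1
        assert unrestricted[0].sites[0].positions == []

    def test_generic_phospho_title_yields_no_event(self, lex):
        doc = abstract("697844", "Phosphorylation, a factor controlling the "
                       "synthesis of L-erythrodihydrobiopterin (BH2).", "")
        assert extract_events(doc, lex, mode="unrestricted") == []

    def test_nbaa_title_known_limitation(self, lex):
        """Without dependency checking, a title co-mentioning cysteine and
        disulfide bonds is extracted — documented limitation."""
        title = ("Overexpression of Reactive Cysteine-Containing "
                 "2-Nitrobenzoate Nitroreductase (NbaA) and Its Mutants "
                 "Alters the Sensitivity of Escherichia coli to Reactive "
                 "Oxygen Species by Reprogramming a Regulatory Network of "
                 "Disulfide-Bonded Proteins.")
        doc = abstract("22564194", title, "")
        events = extract_events(doc, lex, mode="abstract_screen")
        assert len(events) == 1
        assert events[0].ptm == "disulfide_bond"
        assert events[0].sites[0].residue == "cysteine"

    def test_both_parts_rule_holds_corpus_wide(self, lex, small_corpus):
        for doc in small_corpus.documents:
            for ev in extract_events(doc, lex, mode="unrestricted"):
                assert ev.sites
                assert ev.trigger.surface

    def test_determinism(self, lex, small_corpus):
        for doc in small_corpus.documents[:40]:
            a = extract_events(doc, lex, mode="abstract_screen")
            b = extract_events(doc, lex, mode="abstract_screen")
            assert a == b

    def test_removing_tokens_removes_all_class_events(self, lex):
        import copy
        doc = abstract("1", "", "STK9 is phosphorylated at serine 21.")
        assert extract_events(doc, lex, mode="abstract_screen")
        crippled = copy.deepcopy(lex)
        crippled.classes["phosphorylation"].filtering_tokens = ["zzzz"]
        assert extract_events(doc, crippled, mode="abstract_screen") == []
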