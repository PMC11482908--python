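"""Seed-site derivation, transcript scanning and prevalence comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirkit import (
    MatureMiRNA,
    SitePrevalenceSummary,
    ValidationError,
    classify_transcripts,
    compare_site_prevalence,
    derive_site_sequences,
    scan_transcript,
)
from mirkit.seed_sites import SITE_TYPES

from oracles import fisher_two_sided, naive_scan, naive_sites

rna_seq = st.text(alphabet="ACGU", min_size=8, max_size=26)
mature22 = st.text(alphabet="ACGU", min_size=22, max_size=22)


class TestDeriveSiteSequences:
    def test_mir317_published_sites(self, mir317):
        """The miR-317-3p mature sequence yields the five published site strings."""
        sites = derive_site_sequences(mir317)
        assert sites.seed == "GAACAC"
        assert sites.as_dict() == {
            "8mer": "UGUGUUCA",
            "7mer-m8": "UGUGUUC",
            "7mer-A1": "GUGUUCA",
            "offset-6mer": "UGUGUU",
            "6mer": "GUGUUC",
        }

    def test_poly_u_mirna_gives_poly_a_sites(self):
        sites = derive_site_sequences(MatureMiRNA("polyU", "UUUUUUUU"))
        assert sites.as_dict() == {
            "8mer": "AAAAAAAA",
            "7mer-m8": "AAAAAAA",
            "7mer-A1": "AAAAAAA",
            "offset-6mer": "AAAAAA",
            "6mer": "AAAAAA",
        }

    def test_random_sequences_match_naive_revcomp_oracle(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGU"), size=22))
            sites = derive_site_sequences(MatureMiRNA("m", seq))
            expected = naive_sites(seq)
            assert sites.seed == expected["seed"]
            for t in SITE_TYPES:
                assert sites.site(t) == expected[t]

    def test_dna_output_and_dna_input(self):
        sites = derive_site_sequences(
            MatureMiRNA("m", "TGAACACAGTGCTAAATGAAAGA"), dna=True
        )
        assert sites.site_8mer == "TGTGTTCA"

    @given(mature22)
    def test_internal_consistency_invariants(self, seq):
        """Prefix/suffix relations among the five site strings hold for any
        valid mature sequence."""
        sites = derive_site_sequences(MatureMiRNA("m", seq))
        assert sites.site_8mer == sites.site_7mer_m8 + "A"
        assert sites.site_7mer_A1 == sites.site_6mer + "A"
        assert sites.site_7mer_m8.endswith(sites.site_6mer)
        assert sites.site_offset6mer[0] == sites.site_8mer[0]
        assert sites.site_8mer.endswith(sites.site_7mer_A1)
        assert len(sites.site_8mer) == 8
        assert len(sites.site_7mer_m8) == len(sites.site_7mer_A1) == 7
        assert len(sites.site_offset6mer) == len(sites.site_6mer) == 6

    @pytest.mark.parametrize(
        "bad", ["UGAACAC"[:6], "UGAACAX", "UGAAC-CAGU"]
    )
    def test_invalid_mirnas_rejected(self, bad):
        with pytest.raises(ValidationError):
            MatureMiRNA("bad", bad)


class TestScanTranscript:
    def test_single_8mer(self, mir317_sites):
        matches = scan_transcript("t1", "AAUGUGUUCAAA", mir317_sites)
        assert [(m.start, m.end, m.site_type, m.matched_seq) for m in matches] == [
            (3, 10, "8mer", "UGUGUUCA")
        ]

    def test_no_seed_complement(self, mir317_sites):
        assert scan_transcript("t2", "CCCCCCCC", mir317_sites) == []

    def test_terminal_core_is_6mer(self, mir317_sites):
        """Flanks outside the transcript count as non-matching."""
        matches = scan_transcript("t3", "GUGUUC", mir317_sites)
        assert [(m.start, m.end, m.site_type) for m in matches] == [(1, 6, "6mer")]

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GUGUGUUCG", [(2, 8, "7mer-m8")]),
            ("GGUGUUCAG", [(2, 8, "7mer-A1")]),
            ("GGUGUUCGG", [(2, 7, "6mer")]),
            ("GUGUGUUGG", [(2, 7, "offset-6mer")]),
            ("UGUGUUCA", [(1, 8, "8mer")]),
        ],
    )
    def test_each_site_class_detected(self, mir317_sites, seq, expected):
        matches = scan_transcript("t", seq, mir317_sites)
        assert [(m.start, m.end, m.site_type) for m in matches] == expected

    def test_offset_6mer_subsumed_by_stronger_site(self, mir317_sites):
        """The offset-6mer inside an 8mer/7mer-m8 span is not double-reported."""
        matches = scan_transcript("t", "AAUGUGUUCAAA", mir317_sites)
        assert [m.site_type for m in matches] == ["8mer"]

    def test_empty_sequence_rejected(self, mir317_sites):
        with pytest.raises(ValidationError):
            scan_transcript("t", "", mir317_sites)

    def test_ambiguity_codes_never_match(self, mir317_sites):
        matches = scan_transcript("t", "AANGUGUUCNAA", mir317_sites)
        # Ns flanking the core block the m8 and A1 upgrades -> plain 6mer
        assert [(m.start, m.end, m.site_type) for m in matches] == [(4, 9, "6mer")]

    def test_dna_and_lowercase_input_accepted(self, mir317_sites):
        matches = scan_transcript("t", "aatgtgttcaaa", mir317_sites)
        assert [(m.start, m.site_type) for m in matches] == [(3, "8mer")]

    @given(st.text(alphabet="ACGU", min_size=0, max_size=400), mature22)
    def test_scanner_equals_naive_oracle(self, seq, mature):
        """Scanner ≡ independent five-string search + precedence, for random
        transcripts and random miRNAs."""
        if not seq:
            return
        sites = derive_site_sequences(MatureMiRNA("m", mature))
        got = {(m.start, m.end, m.site_type) for m in scan_transcript("t", seq, sites)}
        assert got == set(naive_scan(seq, mature))

    def test_scanner_equals_naive_oracle_long_sequences(self, rng, mir317):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), size=5000))
            sites = derive_site_sequences(mir317)
            got = {
                (m.start, m.end, m.site_type) for m in scan_transcript("t", seq, sites)
            }
            assert got == set(naive_scan(seq, mir317.sequence))

    @given(st.text(alphabet="ACGU", min_size=6, max_size=120), st.text(alphabet="ACGU", min_size=1, max_size=40))
    def test_appending_never_removes_interior_matches(self, seq, tail):
        """Monotonicity: extending a transcript 3' keeps every match that did
        not touch the old boundary."""
        sites = derive_site_sequences(MatureMiRNA("m", "UGAACACAGUGCUAAAUGAAAGA"))
        before = {
            (m.start, m.end, m.site_type)
            for m in scan_transcript("t", seq, sites)
            if m.end < len(seq)  # interior: boundary reclassification allowed
        }
        after = {
            (m.start, m.end, m.site_type) for m in scan_transcript("t", seq + tail, sites)
        }
        assert before <= after


class TestClassifyTranscripts:
    def test_planted_sites_flagged_exactly(self, mir317_sites, tmp_path):
        from mirkit.io import write_fasta
        from mirkit.simulate import SimulationConfig, make_transcripts

        cfg = SimulationConfig(
            rng_seed=7,
            n_transcripts=20,
            site_counts={"8mer": 2, "7mer-m8": 1, "7mer-A1": 2, "offset-6mer": 1, "6mer": 1},
        )
        records, truth = make_transcripts(cfg)
        fasta = tmp_path / "t.fasta"
        write_fasta(records, fasta)
        table = classify_transcripts(fasta, mir317_sites).set_index("transcript_id")
        expected = truth.set_index("transcript_id")["site_type"] != "."
        assert len(table) == 20
        assert (table["has_site"] == expected).all()

    def test_empty_fasta(self, mir317_sites, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        assert classify_transcripts(fasta, mir317_sites).empty

    def test_record_that_is_exactly_the_8mer(self, mir317_sites):
        table = classify_transcripts([("only", "UGUGUUCA")], mir317_sites)
        assert bool(table.loc[0, "has_site"])
        assert int(table.loc[0, "n_8mer"]) == 1
        assert int(table.loc[0, "n_sites"]) == 1

    def test_duplicate_ids_rejected(self, mir317_sites):
        with pytest.raises(ValidationError, match="dup"):
            classify_transcripts([("dup", "ACGU"), ("dup", "ACGU")], mir317_sites)


class TestCompareSitePrevalence:
    def test_balanced_table_p_is_one(self):
        a = SitePrevalenceSummary("a", 2, 1)
        b = SitePrevalenceSummary("b", 2, 1)
        res = compare_site_prevalence(a, b)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_lncrna_prevalence_table_matches_enumeration(self):
        """38/140 upregulated vs 18/52 downregulated lncRNAs with sites."""
        up = SitePrevalenceSummary("up", 140, 38)
        down = SitePrevalenceSummary("down", 52, 18)
        res = compare_site_prevalence(up, down)
        exact = float(fisher_two_sided(38, 102, 18, 34))
        assert res["p_value"] == pytest.approx(exact, rel=1e-9)
        assert res["table"] == ((38, 102), (18, 34))

    def test_all_small_tables_match_enumeration(self):
        """Fisher p agrees with exact hypergeometric enumeration on every
        2×2 table with margins ≤ 12."""
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        if (a + b) == 0 or (c + d) == 0:
                            continue
                        res = compare_site_prevalence(
                            SitePrevalenceSummary("a", a + b, a),
                            SitePrevalenceSummary("b", c + d, c),
                        )
                        exact = float(fisher_two_sided(a, b, c, d))
                        assert res["p_value"] == pytest.approx(exact, abs=1e-12)

    def test_zero_cells_flagged(self):
        res = compare_site_prevalence(
            SitePrevalenceSummary("a", 5, 5), SitePrevalenceSummary("b", 5, 2)
        )
        assert res["odds_ratio_degenerate"]
        assert res["odds_ratio"] == float("inf")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            SitePrevalenceSummary("a", 5, -1)
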