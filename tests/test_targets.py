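"""Seed-complementary site scanning and prediction-table loading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseedcost import (
    MatureMiRNA,
    SeedRegion,
    UTRSequence,
    extract_seed,
    load_prediction_table,
    predict_targets,
    read_utr_fasta,
    reverse_complement,
    seed_match_sites,
)

rna_strings = st.text(alphabet="ACGU", min_size=0, max_size=60)

SEED = SeedRegion(mirna_id="hsa-miR-429", seed="AAUACUG")
CORE_MATCH = "AGUAUU"  # revcomp of seed nts 1-6 (AAUACU)
FULL_MATCH = "CAGUAUU"  # revcomp of the full 7-nt seed
# backgrounds verified free of any match windows for SEED
BG = "GGGGGG"


def naive_sites(seed: str, seq: str, site_types: set[str]) -> list[tuple[str, int, int]]:
    """Direct window-equality oracle with the 8mer > 7mer > 6mer precedence.

    Returns (site_type, start_1based, end_1based) tuples; independent of the
    scanner: every window is compared against the literal pattern.
    """
    core = reverse_complement(seed[:6])
    m8 = reverse_complement(seed[6])
    out = []
    for i in range(len(seq)):
        if seq[i : i + 6] != core:
            continue
        has_m8 = i >= 1 and seq[i - 1 : i] == m8
        has_a1 = seq[i + 6 : i + 7] == "A"
        if has_m8 and has_a1:
            best, s, e = "8mer", i - 1, i + 7
        elif has_m8:
            best, s, e = "7mer-m8", i - 1, i + 6
        elif has_a1:
            best, s, e = "7mer-A1", i, i + 7
        else:
            best, s, e = "6mer", i, i + 6
        if best in site_types:
            out.append((best, s + 1, e))
    return out


class TestReverseComplement:
    def test_seed_complement(self):
        assert reverse_complement("AAUACUG") == "CAGUAUU"

    def test_empty(self):
        assert reverse_complement("") == ""

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGN")

    @given(s=rna_strings)
    @settings(derandomize=True, max_examples=200)
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s


class TestSeedMatchSites:
    def test_planted_7mer_m8_found_once(self):
        utr = UTRSequence("g1", BG + FULL_MATCH + BG)
        sites = seed_match_sites(SEED, utr, site_types={"7mer-m8"})
        assert len(sites) == 1
        (site,) = sites
        assert (site.site_type, site.start, site.end) == ("7mer-m8", 7, 13)

    def test_no_match_returns_empty(self):
        assert seed_match_sites(SEED, UTRSequence("g1", BG * 5)) == []

    def test_8mer_reported_once_not_as_constituent_7mers(self):
        utr = UTRSequence("g1", BG + FULL_MATCH + "A" + BG)
        sites = seed_match_sites(SEED, utr, site_types={"8mer", "7mer-m8", "7mer-A1"})
        assert [s.site_type for s in sites] == ["8mer"]

    def test_7mer_a1_requires_following_a(self):
        utr = UTRSequence("g1", BG + CORE_MATCH + "A" + BG)
        sites = seed_match_sites(SEED, utr, site_types={"7mer-A1"})
        assert [s.site_type for s in sites] == ["7mer-A1"]
        no_a = UTRSequence("g2", BG + CORE_MATCH + "G" + BG)
        assert seed_match_sites(SEED, no_a, site_types={"7mer-A1"}) == []

    def test_6mer_only_when_requested(self):
        utr = UTRSequence("g1", BG + CORE_MATCH + "G" + BG)
        assert seed_match_sites(SEED, utr, site_types={"8mer", "7mer-m8", "7mer-A1"}) == []
        assert [s.site_type for s in seed_match_sites(SEED, utr, site_types={"6mer"})] == ["6mer"]

    def test_empty_site_types_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            seed_match_sites(SEED, UTRSequence("g1", BG), site_types=set())

    def test_overlapping_windows_each_reported(self):
        # CAGUAU CAGUAU -> two core occurrences, each its own site
        utr = UTRSequence("g1", BG + CORE_MATCH + CORE_MATCH + BG)
        sites = seed_match_sites(SEED, utr, site_types={"6mer", "7mer-m8", "7mer-A1", "8mer"})
        assert len(sites) == 2
        assert sites[0].start < sites[1].start

    @given(data=st.data())
    @settings(derandomize=True, max_examples=200)
    def test_agrees_with_naive_window_oracle(self, data):
        seed_str = data.draw(st.text(alphabet="ACGU", min_size=7, max_size=7))
        # AU-rich background makes chance matches common enough to exercise
        seq = data.draw(st.text(alphabet="AUCG" + "AU" * 3, min_size=6, max_size=120))
        types = {"8mer", "7mer-m8", "7mer-A1", "6mer"}
        got = seed_match_sites(SeedRegion("m", seed_str), UTRSequence("g", seq), types)
        assert [(s.site_type, s.start, s.end) for s in got] == naive_sites(seed_str, seq, types)


class TestPredictTargets:
    def test_identical_seeds_identical_sets(self):
        panel = [
            MatureMiRNA(id="a", sequence="UAAUACUGUCUG"),
            MatureMiRNA(id="b", sequence="GAAUACUGCCAA"),  # same seed AAUACUG
        ]
        assert extract_seed(panel[0]).seed == extract_seed(panel[1]).seed
        utrs = [UTRSequence("g1", BG + FULL_MATCH + BG), UTRSequence("g2", BG * 4)]
        sets = predict_targets(panel, utrs)
        assert sets["a"].genes == sets["b"].genes == {"g1"}

    def test_min_sites_threshold_excludes_single_site_gene(self):
        panel = [MatureMiRNA(id="a", sequence="UAAUACUGUCUG")]
        one = UTRSequence("g1", BG + FULL_MATCH + BG)
        two = UTRSequence("g2", BG + FULL_MATCH + BG + FULL_MATCH + BG)
        sets = predict_targets(panel, [one, two], min_sites=2)
        assert sets["a"].genes == {"g2"}

    def test_membership_invariant_to_utr_order(self):
        panel = [MatureMiRNA(id="a", sequence="UAAUACUGUCUG")]
        utrs = [UTRSequence("g1", BG + FULL_MATCH + BG), UTRSequence("g2", BG * 4)]
        assert (
            predict_targets(panel, utrs)["a"].genes
            == predict_targets(panel, utrs[::-1])["a"].genes
        )

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            predict_targets([], [UTRSequence("g", BG)])


class TestPredictionTables:
    def _write(self, tmp_path, rows, header="mirna_id\tgene_symbol\tmirsvr_score"):
        path = tmp_path / "pred.tsv"
        path.write_text(header + "\n" + "".join(r + "\n" for r in rows))
        return path

    def test_mirsvr_threshold_is_strict(self, tmp_path):
        path = self._write(
            tmp_path,
            ["m1\tGENE1\t-0.5", "m1\tGENE2\t-0.1", "m1\tGENE3\t-0.2"],
        )
        sets = load_prediction_table(path, dialect="mirsvr")
        # kept iff score strictly below -0.2: -0.5 in, -0.1 and exactly -0.2 out
        assert sets["m1"].genes == {"GENE1"}

    def test_duplicate_rows_collapse(self, tmp_path):
        path = self._write(tmp_path, ["m1\tGENE1\t-0.9", "m1\tGENE1\t-0.8"])
        assert load_prediction_table(path, "mirsvr")["m1"].genes == {"GENE1"}

    def test_two_column_keeps_all(self, tmp_path):
        path = self._write(
            tmp_path, ["m1\tGENE1", "m1\tGENE2", "m2\tGENE1"], header="mirna_id\tgene_symbol"
        )
        sets = load_prediction_table(path, dialect="two_column")
        assert sets["m1"].genes == {"GENE1", "GENE2"}
        assert sets["m2"].provenance == "table:two_column"

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = self._write(tmp_path, ["m1\tGENE1\t-0.5", "m1\tGENE2"])
        with pytest.raises(ValueError, match=":3"):
            load_prediction_table(path, "mirsvr")

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            load_prediction_table(self._write(tmp_path, []), "targetscan")


def test_read_utr_fasta_roundtrip(tmp_path):
    path = tmp_path / "utrs.fa"
    path.write_text(">g1\nGGGTTTCAGTATT\n>g2\nCCCCCC\n")
    utrs = read_utr_fasta(path)
    assert [u.gene_id for u in utrs] == ["g1", "g2"]
    assert utrs[0].sequence == "GGGUUUCAGUAUU"  # DNA input canonicalized
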