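import random

import pytest

import dnaquine as dq
from dnaquine.annotate import levenshtein
from dnaquine.errors import SearchError, SelectorError, FeatureError
from conftest import random_molecule, random_sequence


class TestSearchSequence:
    def test_palindromic_query_reports_both_strands(self):
        d = dq.from_sequence("TTGAATTCAA", "linear")
        hits = dq.search_sequence(d, "GAATTC")
        assert [(m.start, m.end, m.strand) for m in hits] == [(2, 8, "+"), (2, 8, "-")]

    def test_origin_spanning_match_on_circular(self):
        d = dq.from_sequence("TTCAAAAGAA", "circular")
        hits = dq.search_sequence(d, "GAATTC", strand="+")
        assert len(hits) == 1
        m = hits[0]
        assert m.start == 7 and m.end == 13 and m.matched_text == "GAATTC"

    def test_hamming_mismatch_budget(self):
        d = dq.from_sequence("TTGACTTCAA", "linear")
        hits = dq.search_sequence(d, "GAATTC", strand="+", max_mismatch=1)
        assert [(m.start, m.end, m.mismatches) for m in hits] == [(2, 8, 1)]
        assert dq.search_sequence(d, "GAATTC", strand="+") == []

    def test_overlapping_matches_all_reported(self):
        d = dq.from_sequence("AAAAA", "linear")
        assert len(dq.search_sequence(d, "AAA", strand="+")) == 3

    def test_iupac_degenerate_query(self):
        d = dq.from_sequence("GGTACC", "linear")
        assert len(dq.search_sequence(d, "GGWACC", strand="+")) == 1
        with pytest.raises(SearchError):
            dq.search_sequence(d, "GGXACC")

    def test_regex_query(self):
        d = dq.from_sequence("ATGAAATGA", "linear")
        hits = dq.search_sequence(d, "ATGA+", strand="+", is_regex=True)
        assert [(m.start, m.end) for m in hits] == [(0, 6), (5, 9)]
        with pytest.raises(SearchError):
            dq.search_sequence(d, "AT(", is_regex=True)

    def test_strand_symmetry_under_flip(self):
        """Matches on the flipped molecule are the strand-swapped,
        coordinate-remapped matches of the original."""
        rng = random.Random(5)
        for _ in range(20):
            d = random_molecule(rng, 80, dq.LINEAR, n_features=0)
            q = random_sequence(rng, 4)
            L = len(d.seq)
            orig = dq.search_sequence(d, q)
            flipped = dq.search_sequence(dq.flip(d), q)
            remapped = sorted(
                (L - m.end, L - m.start, "+" if m.strand == "-" else "-")
                for m in orig
            )
            assert remapped == sorted((m.start, m.end, m.strand) for m in flipped)


class TestFindReSites:
    def test_ecoRI_offsets_on_circular(self, ):
        d = dq.from_sequence("AAGAATTCTT", "circular")
        enz = dq.load_enzymes()["EcoRI"]
        assert dq.find_re_sites(d, enz) == [dq.CutSpec(3, 7, "EcoRI")]

    def test_no_site_gives_empty_list(self):
        d = dq.from_sequence("AAAATTTT", "linear")
        assert dq.find_re_sites(d, dq.load_enzymes()["BamHI"]) == []

    def test_type_iis_site_near_linear_end_is_discarded(self):
        bsa = dq.load_enzymes()["BsaI"]
        d = dq.from_sequence("AAAA" + "GGTCTC" + "AA", "linear")  # cuts at 11/15 > length
        assert dq.find_re_sites(d, bsa) == []
        d2 = dq.from_sequence("AAAA" + "GGTCTC" + "A" * 10, "linear")
        assert dq.find_re_sites(d2, bsa) == [dq.CutSpec(11, 15, "BsaI")]

    def test_minus_strand_site_mirror_rule(self):
        bsa = dq.load_enzymes()["BsaI"]
        site_rc = dq.reverse_complement("GGTCTC")
        d = dq.from_sequence("A" * 10 + site_rc + "AAAA", "linear")
        # site on minus strand at [10,16): cuts upstream of it
        (c,) = dq.find_re_sites(d, bsa)
        assert (c.top_cut, c.bottom_cut) == (16 - 11, 16 - 7)

    def test_palindromic_enzyme_reports_each_site_once(self):
        d = dq.from_sequence("TTGAATTCAATTGAATTCAA", "linear")
        assert len(dq.find_re_sites(d, dq.load_enzymes()["EcoRI"])) == 2


class TestSearchFeature:
    def test_key_and_fuzzy_value_matching(self, lut):
        cds = dq.search_feature(lut, dq.FeatureQuery(key_pattern="CDS"))
        assert len(cds) == 4
        hit = dq.search_feature(
            lut, dq.FeatureQuery(value_pattern="GFP0O", mode="fuzzy", max_edits=1)
        )
        assert {f.qualifier("label") for f in hit} == {"GFP00", "GFP01"}

    def test_no_match_returns_empty(self, lut):
        assert dq.search_feature(lut, dq.FeatureQuery(key_pattern="rRNA")) == []

    def test_levenshtein_reference_values(self):
        assert levenshtein("Cas9(D10A)", "Cas9(D10)A") == 2  # transposition = 2 edits
        assert levenshtein("Cas9(D10A)", "Cas9(D10A)") == 0
        assert levenshtein("kitten", "sitting") == 3


class TestEditSequence:
    BASE = dict(
        seq="AAACCCGGGTTT",
        features=[dq.Feature("CDS", dq.Location.single(3, 9, "+"), (("label", "x"),))],
    )

    def mol(self):
        return dq.from_sequence(self.BASE["seq"], "linear", features=self.BASE["features"])

    def test_equal_length_substitution_keeps_features(self):
        out = dq.edit_sequence(self.mol(), (4, 6), "TT")
        assert out.seq == "AAACTTGGGTTT"
        assert out.features[0].location.segments == ((3, 9),)
        assert out.features[0].qualifier("broken_piece") is None

    def test_deletion_breaks_overlapping_feature(self):
        out = dq.edit_sequence(self.mol(), (7, 10), "")
        (piece,) = [f for f in out.features if f.key == "CDS"]
        assert piece.qualifier("broken_piece") is not None
        assert piece.qualifier("original_span") == "0..4"

    def test_insertion_between_features_shifts_downstream(self):
        d = dq.from_sequence(
            "AAACCCGGGTTT", "linear",
            features=[
                dq.Feature("CDS", dq.Location.single(0, 3, "+"), ()),
                dq.Feature("CDS", dq.Location.single(9, 12, "+"), ()),
            ],
        )
        out = dq.edit_sequence(d, (5, 5), "ACGT")
        locs = sorted(f.location.segments[0] for f in out.features)
        assert locs == [(0, 3), (13, 16)]
        assert all(f.qualifier("broken_piece") is None for f in out.features)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(FeatureError):
            dq.edit_sequence(self.mol(), (5, 99), "A")


class TestEditFeature:
    def test_create_remove_update(self):
        d = dq.from_sequence("A" * 80, "linear")
        d = dq.edit_feature(d, "create",
                            ("CDS", dq.Location.single(10, 70, "+"), (("label", "eGFP"),)))
        assert d.features[-1].feature_id
        d = dq.edit_feature(d, "create",
                            ("primer_bind", dq.Location.single(0, 18, "+"), ()))
        d2 = dq.edit_feature(d, "remove", dq.FeatureQuery(key_pattern="primer_bind"))
        assert [f.key for f in d2.features] == ["CDS"]
        fid = d2.features[0].feature_id
        d3 = dq.edit_feature(
            d2, "update",
            (dq.FeatureQuery(value_pattern="eGFP"), {"qualifier_updates": {"label": "sfGFP"}}),
        )
        assert d3.features[0].feature_id == fid
        assert d3.features[0].qualifier("label") == "sfGFP"

    def test_zero_match_selector_errors(self):
        d = dq.from_sequence("ATGC", "linear")
        with pytest.raises(SelectorError):
            dq.edit_feature(d, "remove", dq.FeatureQuery(key_pattern="CDS"))

    def test_out_of_bounds_create_rejected(self):
        d = dq.from_sequence("ATGC", "linear")
        with pytest.raises(FeatureError):
            dq.edit_feature(d, "create", ("CDS", dq.Location.single(2, 9, "+"), ()))
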