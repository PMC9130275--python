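import random

import pytest

import dnaquine as dq
from dnaquine.errors import CutError, EndModificationError, IncompatibleEndsError
from conftest import random_molecule, random_sequence


def top_concat(frags):
    return "".join(f.seq for f in frags)


class TestCut:
    def test_blunt_cut_linear(self):
        d = dq.from_sequence("AAAGGGTTT", "linear")
        a, b = dq.cut(d, dq.CutSpec(3, 3))
        assert (a.seq, b.seq) == ("AAA", "GGGTTT")
        for end in (a.left_end, a.right_end, b.left_end, b.right_end):
            assert end.kind == dq.BLUNT

    def test_sticky_cut_circular_ecoRI(self):
        d = dq.from_sequence("AAGAATTCTT", "circular")
        (f,) = dq.cut(d, dq.CutSpec(3, 7, "EcoRI"))
        assert f.seq == "AATTCTTAAG"
        assert f.left_end == dq.EndStructure("five_prime_overhang", "AATT")
        assert f.right_end == dq.EndStructure("five_prime_overhang", "AATT")

    def test_feature_spanning_cut_is_broken_with_shared_original_id(self):
        d = dq.from_sequence(
            "AAACCCGGGTTT", "linear",
            features=[dq.Feature("CDS", dq.Location.single(2, 10, "+"), (("label", "x"),))],
        )
        orig_id = d.features[0].feature_id
        a, b = dq.cut(d, dq.CutSpec(6, 6))
        pa = [f for f in a.features if f.qualifier("broken_piece")]
        pb = [f for f in b.features if f.qualifier("broken_piece")]
        assert len(pa) == len(pb) == 1
        assert pa[0].qualifier("original_id") == pb[0].qualifier("original_id") == orig_id

    def test_cut_errors(self):
        d = dq.from_sequence("AAAGGGTTT", "linear")
        with pytest.raises(CutError):
            dq.cut(d)
        with pytest.raises(CutError):
            dq.cut(d, dq.CutSpec(0, 0))
        with pytest.raises(CutError):
            dq.cut(d, dq.CutSpec(2, 6), dq.CutSpec(4, 8))  # overlapping overhangs

    def test_conservation_of_top_strand(self):
        rng = random.Random(7)
        for _ in range(20):
            d = random_molecule(rng, 100, dq.LINEAR)
            cuts = sorted(rng.sample(range(10, 90), 3))
            frags = dq.cut(d, *(dq.CutSpec(c, c) for c in cuts))
            assert top_concat(frags) == d.seq

    def test_rotation_invariance_of_circular_cutting(self):
        rng = random.Random(11)
        seq = random_sequence(rng, 60)
        k = 17
        a = dq.from_sequence(seq, "circular")
        b = dq.from_sequence(seq[k:] + seq[:k], "circular")
        fa = dq.cut(a, dq.CutSpec(5, 5), dq.CutSpec(30, 30))
        fb = dq.cut(b, dq.CutSpec((5 - k) % 60, (5 - k) % 60),
                    dq.CutSpec((30 - k) % 60, (30 - k) % 60))
        assert sorted(f.seq for f in fa) == sorted(f.seq for f in fb)


class TestCrop:
    def test_crop_linear(self):
        d = dq.from_sequence("AAAGGGTTT", "linear")
        assert dq.crop(d, dq.CutSpec(3, 3), dq.CutSpec(6, 6)).seq == "GGG"

    def test_crop_circular_wrap(self):
        d = dq.from_sequence("AAGAATTCTT", "circular")
        assert dq.crop(d, dq.CutSpec(8, 8), dq.CutSpec(2, 2)).seq == "TTAA"

    def test_crop_empty_segment_errors(self):
        d = dq.from_sequence("AAAGGGTTT", "linear")
        with pytest.raises(CutError):
            dq.crop(d, dq.CutSpec(3, 3), dq.CutSpec(3, 3))


class TestFlip:
    def test_flip_blunt(self):
        d = dq.from_sequence("ATGC", "linear")
        assert dq.flip(d).seq == "GCAT"

    def test_flip_feature_coordinates(self):
        d = dq.from_sequence(
            "ATGC", "linear",
            features=[dq.Feature("CDS", dq.Location.single(1, 3, "+"), ())],
        )
        f = dq.flip(d).features[0]
        assert f.location.segments == ((1, 3),) and f.location.strand == "-"

    def test_flip_involution_random(self):
        rng = random.Random(23)
        for _ in range(20)            :
            d = random_molecule(rng, 80, rng.choice([dq.LINEAR, dq.CIRCULAR]))
            ff = dq.flip(dq.flip(d))
            assert ff.seq == d.seq
            assert {(f.location.segments, f.location.strand) for f in ff.features} == \
                   {(f.location.segments, f.location.strand) for f in d.features}

    def test_flip_preserves_overhang_kind(self):
        d = dq.from_sequence("AAGAATTCTTGG", "linear")
        left, right = dq.cut(d, dq.CutSpec(3, 7))
        flipped = dq.flip(right)
        assert flipped.right_end == right.left_end
        assert flipped.left_end == right.right_end


class TestJoin:
    def test_blunt_join(self):
        a = dq.from_sequence("AAA", "linear")
        b = dq.from_sequence("TTT", "linear")
        assert dq.join([a, b], "linear").seq == "AAATTT"

    def test_sticky_compatibility(self):
        assert dq.ends_compatible(
            dq.EndStructure("five_prime_overhang", "AATT"),
            dq.EndStructure("five_prime_overhang", "AATT"),
        )
        assert not dq.ends_compatible(
            dq.EndStructure("five_prime_overhang", "AATT"),
            dq.EndStructure("five_prime_overhang", "GATC"),
        )
        assert not dq.ends_compatible(
            dq.EndStructure("five_prime_overhang", "AATT"),
            dq.EndStructure("three_prime_overhang", "AATT"),
        )

    def test_n_overhang_never_anneals(self):
        assert not dq.ends_compatible(
            dq.EndStructure("five_prime_overhang", "ANT"),
            dq.EndStructure("five_prime_overhang", "ANT"),
        )

    def test_incompatible_junction_reports_index(self):
        d = dq.from_sequence("AAGAATTCTTGG", "linear")
        left, _right = dq.cut(d, dq.CutSpec(3, 7))
        blunt = dq.from_sequence("CCCC", "linear")
        with pytest.raises(IncompatibleEndsError, match="junction 0"):
            dq.join([left, blunt], "linear")

    def test_cut_join_inverse_linear(self):
        rng = random.Random(31)
        for _ in range(20):
            d = random_molecule(rng, 100, dq.LINEAR)
            pos = rng.randrange(20, 80)
            off = rng.randrange(-4, 5)
            frags = dq.cut(d, dq.CutSpec(pos, pos + off))
            back = dq.join(frags, "linear")
            assert back.seq == d.seq
            assert {f.feature_id for f in back.features} == {f.feature_id for f in d.features}
            assert all(f.qualifier("broken_piece") is None for f in back.features)

    def test_cut_join_inverse_circular(self):
        rng = random.Random(37)
        for _ in range(20):
            d = random_molecule(rng, 100, dq.CIRCULAR)
            p1, p2 = sorted(rng.sample(range(5, 95), 2))
            if p2 - p1 < 8:
                continue
            frags = dq.cut(d, dq.CutSpec(p1, p1 + 3), dq.CutSpec(p2, p2 + 3))
            back = dq.join(frags, "circular")
            assert back.seq == d.seq[p1:] + d.seq[:p1]
            assert {f.feature_id for f in back.features} == {f.feature_id for f in d.features}

    def test_join_flip_antihomomorphism(self):
        rng = random.Random(41)
        a = random_molecule(rng, 60, dq.LINEAR)
        b = random_molecule(rng, 50, dq.LINEAR)
        lhs = dq.join([dq.flip(b), dq.flip(a)], "linear")
        rhs = dq.flip(dq.join([a, b], "linear"))
        assert lhs.seq == rhs.seq
        assert {(f.location.segments, f.location.strand) for f in lhs.features} == \
               {(f.location.segments, f.location.strand) for f in rhs.features}

    def test_cross_molecule_restoration(self):
        """Two pieces of one feature, carried by fragments of two different
        molecules, are restored when joined in original order."""
        seq = "AAACCCGGGTTTACGTACGTAAACCCGGGTTT"
        feats = [dq.Feature("CDS", dq.Location.single(4, 28, "+"), (("label", "big"),))]
        d1 = dq.from_sequence(seq, "linear", name="m1", features=feats)
        d2 = dq.from_sequence(seq, "linear", name="m2", features=feats)
        # identical feature_id in both molecules (same content hash inputs)
        assert d1.features[0].feature_id == d2.features[0].feature_id
        left = dq.cut(d1, dq.CutSpec(16, 16))[0]
        right = dq.cut(d2, dq.CutSpec(16, 16))[1]
        back = dq.join([left, right], "linear")
        (cds,) = [f for f in back.features if f.key == "CDS"]
        assert cds.qualifier("broken_piece") is None
        assert cds.feature_id == d1.features[0].feature_id
        assert cds.location.segments == ((4, 28),)


class TestModifyEnds:
    def test_extend_left_top(self):
        d = dq.from_sequence("CCGG", "linear")
        e = dq.modify_ends(d, dq.EndModification("left", "extend", "top", seq="AATT"))
        assert e.seq == "AATTCCGG"
        assert e.left_end == dq.EndStructure("five_prime_overhang", "AATT")

    def test_trim_left_bottom_exposes_five_prime(self):
        d = dq.from_sequence("AATTCCGG", "linear")
        t = dq.modify_ends(d, dq.EndModification("left", "trim", "bottom", length=4))
        assert t.left_end == dq.EndStructure("five_prime_overhang", "AATT")

    def test_trim_beyond_duplex_errors(self):
        d = dq.from_sequence("AATTCCGG", "linear")
        with pytest.raises(EndModificationError):
            dq.modify_ends(d, dq.EndModification("left", "trim", "bottom", length=8))

    def test_circular_input_rejected(self):
        d = dq.from_sequence("AATTCCGG", "circular")
        with pytest.raises(EndModificationError):
            dq.modify_ends(d, dq.EndModification("left", "extend", "top", seq="A"))

    def test_complementary_extension_restores_blunt(self):
        d = dq.from_sequence("CCGG", "linear")
        e = dq.modify_ends(
            d,
            dq.EndModification("left", "extend", "top", seq="AATT"),
            dq.EndModification("left", "extend", "bottom", seq=dq.reverse_complement("AATT")),
        )
        assert e.seq == "AATTCCGG" and e.left_end.kind == dq.BLUNT

    def test_mismatched_extension_rejected(self):
        d = dq.from_sequence("CCGG", "linear")
        e = dq.modify_ends(d, dq.EndModification("left", "extend", "top", seq="AATT"))
        with pytest.raises(EndModificationError):
            dq.modify_ends(e, dq.EndModification("left", "extend", "bottom", seq="GGGG"))

    def test_right_side_mirrors_left_via_flip(self):
        rng = random.Random(43)
        for _ in range(10):
            d = random_molecule(rng, 60, dq.LINEAR, n_features=1)
            text = random_sequence(rng, 6)
            direct = dq.modify_ends(d, dq.EndModification("right", "extend", "top", seq=text))
            mirrored = dq.flip(
                dq.modify_ends(dq.flip(d), dq.EndModification("left", "extend", "bottom", seq=text))
            )
            assert direct.seq == mirrored.seq
            assert direct.right_end == mirrored.right_end

    def test_gibson_style_trims_make_compatible_ends(self):
        overlap = "ACGTACGTACGTACGTACGT"
        up = dq.from_sequence("AAACCC" + overlap, "linear")
        down = dq.from_sequence(overlap + "GGGTTT", "linear")
        up_t = dq.modify_ends(up, dq.EndModification("right", "trim", "top", length=20))
        down_t = dq.modify_ends(down, dq.EndModification("left", "trim", "bottom", length=20))
        assert dq.ends_compatible(up_t.right_end, down_t.left_end)
        product = dq.join([up_t, down_t], "linear")
        assert product.seq == "AAACCC" + overlap + "GGGTTT"
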