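import random

import pytest

import dnaquine as dq
from dnaquine.errors import AssemblyError, CircuitError, PrimerError
from dnaquine.recipes import apply_recombinase, load_recombinase_sites
from conftest import random_sequence

SITES = load_recombinase_sites()


def unique_template(rng, n):
    """Random circular template whose every 18-mer is unique on both strands
    (draw-and-check)."""
    while True:
        seq = random_sequence(rng, n)
        wins = set()
        ok = True
        doubled = seq + seq[:17]
        for i in range(n):
            w = doubled[i : i + 18]
            if w in wins or dq.reverse_complement(w) in wins:
                ok = False
                break
            wins.add(w)
        if ok:
            return seq


class TestPcr:
    def test_product_length_law_randomized(self):
        rng = random.Random(13)
        for _ in range(10):
            seq = unique_template(rng, 300)
            t = dq.from_sequence(seq, "circular", name="t")
            fs = rng.randrange(0, 300)
            span = rng.randrange(80, 200)
            re_ = fs + span
            ft = random_sequence(rng, rng.randrange(0, 12))
            rt = random_sequence(rng, rng.randrange(0, 12))
            doubled = seq + seq
            fwd = dq.Primer(ft + doubled[fs : fs + 18], 18)
            rev = dq.Primer(
                dq.reverse_complement(doubled[re_ - 18 : re_]) if not rt
                else rt + dq.reverse_complement(doubled[re_ - 18 : re_]),
                18,
            )
            product = dq.simulate_pcr(t, fwd, rev)
            assert len(product.seq) == len(ft) + span + len(rt)
            assert product.left_end.kind == dq.BLUNT and product.right_end.kind == dq.BLUNT

    def test_tailless_primers_give_exact_span(self):
        t = dq.from_sequence("A" * 5 + unique_template(random.Random(3), 100), "linear")
        fwd = dq.Primer(t.seq[10:28], 18)
        rev = dq.Primer(dq.reverse_complement(t.seq[62:80]), 18)
        product = dq.simulate_pcr(t, fwd, rev)
        assert product.seq == t.seq[10:80]

    def test_ambiguous_and_missing_binding(self):
        t = dq.from_sequence("ATGC" * 30, "linear")
        with pytest.raises(PrimerError, match="ambiguous|positions"):
            dq.simulate_pcr(t, dq.Primer("ATGC" * 5, 18),
                            dq.Primer(dq.reverse_complement("ATGC" * 5), 18))
        u = dq.from_sequence(unique_template(random.Random(5), 100), "linear")
        with pytest.raises(PrimerError, match="does not anneal"):
            dq.simulate_pcr(u, dq.Primer("G" * 18, 18), dq.Primer("C" * 18, 18))

    def test_wrong_orientation_rejected(self):
        u = dq.from_sequence(unique_template(random.Random(8), 120), "linear")
        fwd = dq.Primer(u.seq[80:98], 18)
        rev = dq.Primer(dq.reverse_complement(u.seq[10:28]), 18)
        with pytest.raises(PrimerError, match="orientation"):
            dq.simulate_pcr(u, fwd, rev)


class TestDigestLigate:
    def test_double_digest_and_religation_round_trip(self, cloning_demo):
        bb = cloning_demo["backbone"]
        enz = dq.load_enzymes()
        frags = dq.digest(bb, enz["EcoRI"], enz["BamHI"])
        assert len(frags) == 2
        back = dq.ligate(frags, "circular")
        # same circle, rotated to the first cut
        assert back.seq in bb.seq + bb.seq
        assert len(back.seq) == len(bb.seq)
        assert {f.feature_id for f in back.features} == {f.feature_id for f in bb.features}

    def test_junction_sites_restored_after_ligation(self, cloning_demo):
        p = cloning_demo["plasmid"]
        assert len(dq.search_sequence(p, "GAATTC", strand="+")) == 1
        assert len(dq.search_sequence(p, "GGATCC", strand="+")) == 1

    def test_absent_enzyme_errors(self):
        d = dq.from_sequence("ATATATATAT", "circular")
        with pytest.raises(AssemblyError, match="BamHI"):
            dq.digest(d, dq.load_enzymes()["BamHI"])

    def test_ligation_records_process_name(self, cloning_demo):
        join_rec = [r for r in cloning_demo["plasmid"].history if r.op_name == "join"][-1]
        assert join_rec.process_name == "ligation"


class TestGibson:
    def _frags(self, rng, k1=20, k2=20):
        a_core, b_core = random_sequence(rng, 80), random_sequence(rng, 50)
        j1, j2 = random_sequence(rng, k1), random_sequence(rng, k2)
        a = dq.from_sequence(j2 + a_core + j1, "linear", name="A")
        b = dq.from_sequence(j1 + b_core + j2, "linear", name="B")
        return a, b

    def test_length_law_circular(self):
        rng = random.Random(17)
        a, b = self._frags(rng)
        product = dq.gibson_assembly([a, b], min_overlap=15)
        assert product.topology == dq.CIRCULAR
        assert len(product.seq) == len(a.seq) + len(b.seq) - 40

    def test_overlap_appears_once(self):
        rng = random.Random(19)
        a, b = self._frags(rng)
        j1 = a.seq[-20:]
        product = dq.gibson_assembly([a, b], min_overlap=15)
        # circular occurrence count: scan one full turn
        assert (product.seq + product.seq[:19]).count(j1) == 1

    def test_short_overlap_rejected_with_best_length(self):
        rng = random.Random(21)
        a, b = self._frags(rng, k1=10, k2=20)
        with pytest.raises(AssemblyError, match="10"):
            dq.gibson_assembly([a, b], min_overlap=15)

    def test_split_cds_restored_across_parents(self, lineage):
        h1 = lineage["h1"]
        (cas,) = [f for f in h1.features if f.qualifier("label") == "Cas9(D10A)-analog"]
        assert cas.qualifier("broken_piece") is None
        assert cas.location.length == 600


class TestRecombinase:
    LOX = SITES["Cre"].site_seq
    P, Q = "TTGACCGGTTAACCGGTTAA", "GGCCAATTGGCCAATTGGTT"
    X = "ACGTACGTACGTACGTACGTACGTACGTAACC"

    def test_excision_same_orientation(self):
        d = dq.from_sequence(self.P + self.LOX + self.X + self.LOX + self.Q, "linear")
        main, by = apply_recombinase(d, SITES["Cre"])
        assert main.seq == self.P + self.LOX + self.Q
        assert len(by) == 1 and by[0].topology == dq.CIRCULAR
        assert by[0].seq == self.LOX + self.X

    def test_excision_conserves_nucleotides(self):
        d = dq.from_sequence(self.P + self.LOX + self.X + self.LOX + self.Q, "linear")
        main, by = apply_recombinase(d, SITES["Cre"])
        assert len(main.seq) + len(by[0].seq) == len(d.seq)

    def test_inversion_opposite_orientation(self):
        d = dq.from_sequence(
            self.P + self.LOX + self.X + dq.reverse_complement(self.LOX) + self.Q, "linear"
        )
        main, by = apply_recombinase(d, SITES["Cre"])
        assert main.seq == (
            self.P + self.LOX + dq.reverse_complement(self.X)
            + dq.reverse_complement(self.LOX) + self.Q
        )
        assert not by and len(main.seq) == len(d.seq)

    def test_flex_style_feature_inversion(self):
        """A FLEx-like switch: a minus-strand CDS between antiparallel sites
        is flipped into the plus orientation."""
        cds_seq = "ATGGCTGCTGCTGCTTAA"
        inner = dq.reverse_complement(cds_seq)
        d = dq.from_sequence(
            self.P + self.LOX + inner + dq.reverse_complement(self.LOX) + self.Q,
            "linear",
            features=[dq.Feature(
                "CDS",
                dq.Location.single(len(self.P) + 34, len(self.P) + 34 + len(inner), "-"),
                (("label", "payload"),),
            )],
        )
        main, _ = apply_recombinase(d, SITES["Cre"])
        (cds,) = [f for f in main.features if f.key == "CDS"]
        assert cds.location.strand == "+"
        s, e = cds.location.segments[0]
        assert main.seq[s:e] == cds_seq

    def test_serine_integrase_one_shot(self):
        phi = SITES["PhiC31"]
        d = dq.from_sequence(self.P + phi.site_seq + self.X + phi.attP + self.Q, "linear")
        main, by = apply_recombinase(d, phi)
        assert phi.attL in main.seq
        assert phi.attR in by[0].seq
        again, by2 = apply_recombinase(main, phi)
        assert again.seq == main.seq and not by2

    def test_fewer_than_two_sites_is_noop(self):
        d = dq.from_sequence(self.P + self.LOX + self.Q, "linear")
        main, by = apply_recombinase(d, SITES["Cre"])
        assert main.seq == d.seq and not by


class TestCallExpression:
    def build(self, order):
        parts, feats, pos = [], [], 0
        for key, strand in order:
            text = "ACGTACGTAC"
            feats.append(dq.Feature(key, dq.Location.single(pos, pos + 10, strand),
                                    (("label", f"{key}{pos}"),)))
            parts.append(text)
            pos += 10
        return dq.from_sequence("".join(parts), "linear", features=feats)

    def test_terminator_blocks(self):
        d = self.build([("promoter", "+"), ("terminator", "+"), ("CDS", "+")])
        assert dq.call_expression(d) is None

    def test_simple_expression(self):
        d = self.build([("promoter", "+"), ("CDS", "+")])
        assert dq.call_expression(d).key == "CDS"

    def test_wrong_orientation_cds_is_transparent(self):
        d = self.build([("promoter", "+"), ("CDS", "-"), ("CDS", "+")])
        hit = dq.call_expression(d)
        assert hit.location.strand == "+" and hit.location.start == 20

    def test_promoter_count_enforced(self):
        d = self.build([("CDS", "+")])
        with pytest.raises(CircuitError):
            dq.call_expression(d)
        d2 = self.build([("promoter", "+"), ("promoter", "+"), ("CDS", "+")])
        with pytest.raises(CircuitError):
            dq.call_expression(d2)

    def test_circular_wraps_one_turn(self):
        d = self.build([("CDS", "+"), ("promoter", "+")])
        circ = dq.from_sequence(d.seq, "circular", features=list(d.features))
        assert dq.call_expression(circ).location.start == 0
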