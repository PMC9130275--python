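"""Deterministic synthetic stand-in materials.

Everything the demonstration protocols need is generated here from a seed:
no external sequence files or database accessions are required.  Three
fixture families mirror the package's three demonstration workflows:

* a donor/backbone plasmid pair (with primers) for classic restriction
  cloning of a fluorescent-protein cassette,
* a plasmid lineage built by PCR + Gibson assembly in two generations, in
  which one CDS is deliberately amplified as two adjacent fragments from
  two different first-generation plasmids and restored on assembly,
* a six-input recombinase look-up-table (LUT) logic circuit with an
  independent analytic oracle for all 64 input patterns.

Identical seeds give byte-identical fixtures.  Random filler is screened
against every restriction recognition text and recombinase site so that no
accidental cut sites or recombination sites arise; primer annealing regions
are screened for uniqueness.  Because the screening loops redraw on
collision, any seed yields a valid fixture.
"""

from __future__ import annotations

import random

from .errors import DnaQuineError
from .model import CIRCULAR, LINEAR, DsDna, Feature, Location, from_sequence, reverse_complement
from .provenance import set_process
from .recipes import (
    Primer,
    digest,
    gibson_assembly,
    ligate,
    load_enzymes,
    load_recombinase_sites,
    simulate_pcr,
)

_BASES = "ACGT"


def _filler(rng: random.Random, n: int, forbidden) -> str:
    """Random sequence of length n containing no forbidden motif on either
    strand (the assembled-molecule boundaries are re-screened separately)."""
    for _ in range(200):
        text = "".join(rng.choice(_BASES) for _ in range(n))
        if not _contains_any(text, forbidden):
            return text
    raise DnaQuineError("filler screening did not converge")


def _contains_any(text: str, forbidden) -> bool:
    for motif in forbidden:
        if motif in text or reverse_complement(motif) in text:
            return True
    return False


def _count_both_strands(text: str, motif: str) -> int:
    rc = reverse_complement(motif)
    n = 0
    for i in range(len(text) - len(motif) + 1):
        win = text[i : i + len(motif)]
        if win == motif or win == rc:
            n += 1
    return n


def _count_circular(text: str, motif: str) -> int:
    if len(text) < len(motif):
        return 0
    return _count_both_strands(text + text[: len(motif) - 1], motif)


# ---------------------------------------------------------------------------
# restriction-cloning fixture

def make_cloning_pair(seed: int):
    """(donor, backbone, fwd, rev): a ~3 kb circular donor carrying an
    eGFP-analog CDS flanked by unique 18-bp primer annealing regions, a
    ~5 kb circular backbone with unique EcoRI and BamHI sites in its cloning
    region, and the two tailed primers.  Neither enzyme cuts anywhere else
    in either molecule."""
    enzymes = load_enzymes()
    eco, bam = enzymes["EcoRI"], enzymes["BamHI"]
    forbidden = [eco.recognition, bam.recognition]
    rng = random.Random(("cloning", seed).__repr__())
    for _attempt in range(50):
        anneal_f = _filler(rng, 18, forbidden)
        anneal_r_top = _filler(rng, 18, forbidden)
        cds = _filler(rng, 720, forbidden)
        parts = [
            _filler(rng, 600, forbidden),   # upstream filler
            anneal_f,
            _filler(rng, 30, forbidden),
            cds,
            _filler(rng, 30, forbidden),
            anneal_r_top,
            _filler(rng, 1580, forbidden),  # downstream filler
        ]
        donor_seq = "".join(parts)
        cds_start = 600 + 18 + 30
        if _count_circular(donor_seq, eco.recognition) or _count_circular(donor_seq, bam.recognition):
            continue
        if _count_circular(donor_seq, anneal_f) != 1 or _count_circular(donor_seq, anneal_r_top) != 1:
            continue
        bb_parts = [
            _filler(rng, 2000, forbidden),
            eco.recognition,
            _filler(rng, 40, forbidden),
            bam.recognition,
            _filler(rng, 2300, forbidden),
            _filler(rng, 600, forbidden),   # marker CDS body
            _filler(rng, 48, forbidden),
        ]
        backbone_seq = "".join(bb_parts)
        if (
            _count_circular(backbone_seq, eco.recognition) != 1
            or _count_circular(backbone_seq, bam.recognition) != 1
        ):
            continue
        donor = from_sequence(
            donor_seq,
            CIRCULAR,
            name="pDonor-eGFP",
            features=[
                Feature(
                    "CDS",
                    Location.single(cds_start, cds_start + 720, "+"),
                    (("label", "eGFP-analog"),),
                )
            ],
        )
        marker_start = 2000 + 6 + 40 + 6 + 2300
        backbone = from_sequence(
            backbone_seq,
            CIRCULAR,
            name="pBackbone",
            features=[
                Feature(
                    "CDS",
                    Location.single(marker_start, marker_start + 600, "+"),
                    (("label", "marker-analog"),),
                )
            ],
        )
        fwd = Primer("ACTG" + eco.recognition + anneal_f, anneal_length=18)
        rev = Primer("TCAG" + bam.recognition + reverse_complement(anneal_r_top), anneal_length=18)
        return donor, backbone, fwd, rev
    raise DnaQuineError("cloning fixture screening did not converge")


def run_cloning_demo(seed: int) -> dict:
    """Execute the full restriction-cloning protocol on the fixture pair:
    PCR the cassette with RE-site tails, double-digest product and backbone
    with EcoRI + BamHI, ligate circular.  Returns the intermediates and the
    final plasmid."""
    donor, backbone, fwd, rev = make_cloning_pair(seed)
    enzymes = load_enzymes()
    eco, bam = enzymes["EcoRI"], enzymes["BamHI"]
    with set_process(
        "PCR amplification",
        "The eGFP-analog cassette was amplified from the donor plasmid with "
        "primers whose 5' tails carry EcoRI and BamHI recognition sites.",
    ):
        product = simulate_pcr(donor, fwd, rev, name="pcr-eGFP")
    with set_process(
        "EcoRI/BamHI double digestion",
        "The PCR product and the destination backbone were both digested "
        "with EcoRI and BamHI.",
    ):
        insert = digest(product, eco, bam)[1]
        keeper = digest(backbone, eco, bam)[1]
    with set_process(
        "ligation",
        "The digested fragments with compatible sticky ends were ligated "
        "into the final circular plasmid.",
    ):
        plasmid = ligate([insert, keeper], CIRCULAR, name="pProduct-eGFP")
    return {
        "donor": donor,
        "backbone": backbone,
        "pcr_product": product,
        "insert": insert,
        "backbone_keeper": keeper,
        "plasmid": plasmid,
        "fwd": fwd,
        "rev": rev,
    }


# ---------------------------------------------------------------------------
# Gibson-lineage fixture

def make_lineage(seed: int) -> dict:
    """A two-generation plasmid lineage built by PCR + Gibson assembly.

    Five root plasmids (r1..r5) feed four first-generation products
    (g1..g4); two second-generation products reuse first-generation parts:
    h1 amplifies the Cas9(D10A)-analog CDS as two adjacent fragments from
    g1 and g2 (the junction overlap lies inside the CDS) and restores it on
    assembly; h2 recombines parts of g2 and g4.  Returns the eleven
    molecules keyed r1..r5, g1..g4, h1, h2, plus "gen1_history": each
    first-generation product's step-id set at the moment that generation was
    complete (later searches keep appending to histories in place).
    """
    enzymes = load_enzymes()
    forbidden = [e.recognition for e in enzymes.values()]
    rng = random.Random(("lineage", seed).__repr__())
    for _attempt in range(50):
        try:
            return _build_lineage(rng, forbidden)
        except DnaQuineError:
            continue
    raise DnaQuineError("lineage fixture screening did not converge")


def _mk_root(rng, forbidden, name, label, cds_len, pre=260, post=260):
    pre_f = _filler(rng, pre, forbidden)
    cds = _filler(rng, cds_len, forbidden)
    post_f = _filler(rng, post, forbidden)
    seq = pre_f + cds + post_f
    feats = [
        Feature("CDS", Location.single(pre, pre + cds_len, "+"), (("label", label),))
    ]
    return from_sequence(seq, CIRCULAR, name=name, features=feats)


def _pcr_span(template: DsDna, start: int, end: int, left_text: str, right_text: str,
              name: str) -> DsDna:
    """PCR the template span [start, end) (circular-aware).  The product top
    strand reads left_text + template[start:end] + right_text; the texts are
    carried by the primer tails."""
    L = len(template.seq)
    doubled = template.seq + template.seq
    f_anneal = doubled[start % L : start % L + 18]
    r_anneal_top = doubled[(end - 18) % L : (end - 18) % L + 18]
    fwd = Primer(left_text + f_anneal, anneal_length=18)
    rev_tail = reverse_complement(right_text) if right_text else ""
    rev = Primer(rev_tail + reverse_complement(r_anneal_top), anneal_length=18)
    return simulate_pcr(template, fwd, rev, name=name)


def _span_around(mol: DsDna, label: str, pad: int) -> tuple[int, int]:
    """The interval covering the CDS with the given label plus pad nt of
    context on each side."""
    for f in mol.features:
        if f.key == "CDS" and f.qualifier("label") == label:
            return f.location.start - pad, f.location.end + pad
    raise DnaQuineError(f"{label!r} not found in {mol.name}")


def _build_lineage(rng, forbidden) -> dict:
    r1 = _mk_root(rng, forbidden, "pRoot-editor", "Cas9(D10A)-analog", 600)
    r2 = _mk_root(rng, forbidden, "pRoot-backboneA", "repliconA-analog", 500)
    r3 = _mk_root(rng, forbidden, "pRoot-backboneB", "repliconB-analog", 500)
    r4 = _mk_root(rng, forbidden, "pRoot-payloadC", "deaminase-analog", 450)
    r5 = _mk_root(rng, forbidden, "pRoot-payloadD", "inhibitor-analog", 450)
    link = {k: _filler(rng, 20, forbidden) for k in ("J1", "J2", "J3", "J4", "J5", "J6")}

    def cassette(root, label, j_left, j_right, name):
        s, e = _span_around(root, label, 80)
        return _pcr_span(root, s, e, link[j_left], link[j_right], name)

    def backbone_part(root, label, j_left, j_right, name):
        s, e = _span_around(root, label, 60)
        return _pcr_span(root, s, e, link[j_left], link[j_right], name)

    with set_process("Assembly of pEdit-A",
                     "The editor cassette of pRoot-editor and the replicon of "
                     "pRoot-backboneA were amplified and joined by Gibson assembly."):
        g1 = gibson_assembly(
            [cassette(r1, "Cas9(D10A)-analog", "J1", "J2", "fragA1"),
             backbone_part(r2, "repliconA-analog", "J2", "J1", "fragA2")],
            min_overlap=15, result_topology=CIRCULAR, name="pEdit-A",
        )
    with set_process("Assembly of pEdit-B",
                     "The editor cassette of pRoot-editor and the replicon of "
                     "pRoot-backboneB were amplified and joined by Gibson assembly."):
        g2 = gibson_assembly(
            [cassette(r1, "Cas9(D10A)-analog", "J3", "J4", "fragB1"),
             backbone_part(r3, "repliconB-analog", "J4", "J3", "fragB2")],
            min_overlap=15, result_topology=CIRCULAR, name="pEdit-B",
        )
    with set_process("Assembly of pEdit-C",
                     "The deaminase payload of pRoot-payloadC was installed on the "
                     "pRoot-backboneA replicon by Gibson assembly."):
        g3 = gibson_assembly(
            [cassette(r4, "deaminase-analog", "J5", "J6", "fragC1"),
             backbone_part(r2, "repliconA-analog", "J6", "J5", "fragC2")],
            min_overlap=15, result_topology=CIRCULAR, name="pEdit-C",
        )
    with set_process("Assembly of pEdit-D",
                     "The inhibitor payload of pRoot-payloadD was installed on the "
                     "pRoot-backboneB replicon by Gibson assembly."):
        g4 = gibson_assembly(
            [cassette(r5, "inhibitor-analog", "J5", "J6", "fragD1"),
             backbone_part(r3, "repliconB-analog", "J6", "J5", "fragD2")],
            min_overlap=15, result_topology=CIRCULAR, name="pEdit-D",
        )

    # Histories grow in place when a molecule is searched later (searches are
    # recorded), so inheritance is asserted against each parent's history as
    # it stood when the first generation was complete.
    gen1_history = {
        name: frozenset(r.step_id for r in mol.history)
        for name, mol in (("g1", g1), ("g2", g2), ("g3", g3), ("g4", g4))
    }

    # second generation: h1 re-amplifies the Cas9-analog CDS as two adjacent
    # blocks from two different parents; the 20-nt Gibson overlap lies inside
    # the CDS, so each fragment carries a broken piece that is restored on
    # assembly.
    def find_cds(mol, label):
        for f in mol.features:
            if f.qualifier("label") == label and f.key == "CDS":
                return f
        raise DnaQuineError(f"{label} not found in {mol.name}")

    cas_g1 = find_cds(g1, "Cas9(D10A)-analog")
    cas_g2 = find_cds(g2, "Cas9(D10A)-analog")
    mid = 300  # split offset within the 600-nt CDS
    with set_process("Assembly of pEdit-E",
                     "The editor CDS was amplified as two adjacent blocks from "
                     "pEdit-A and pEdit-B (the Gibson overlap lies inside the CDS) "
                     "and assembled with the pEdit-C replicon part."):
        fa = _pcr_span(g1, cas_g1.location.start - 60,
                       cas_g1.location.start + mid + 20, link["J1"], "", "fragE1")
        fb = _pcr_span(g2, cas_g2.location.start + mid,
                       cas_g2.location.end + 60, "", link["J6"], "fragE2")
        fc = backbone_part(g3, "repliconA-analog", "J6", "J1", "fragE3")
        h1 = gibson_assembly([fa, fb, fc], min_overlap=15,
                             result_topology=CIRCULAR, name="pEdit-E")
    with set_process("Assembly of pEdit-F",
                     "The editor cassette of pEdit-B was recombined with the "
                     "pEdit-D replicon part by Gibson assembly."):
        fd = _pcr_span(g2, cas_g2.location.start - 70, cas_g2.location.end + 70,
                       link["J2"], link["J5"], "fragF1")
        fe = backbone_part(g4, "repliconB-analog", "J5", "J2", "fragF2")
        h2 = gibson_assembly([fd, fe], min_overlap=15,
                             result_topology=CIRCULAR, name="pEdit-F")

    out = {"r1": r1, "r2": r2, "r3": r3, "r4": r4, "r5": r5,
           "g1": g1, "g2": g2, "g3": g3, "g4": g4, "h1": h1, "h2": h2,
           "gen1_history": gen1_history}
    restored = find_cds(h1, "Cas9(D10A)-analog")
    if restored.qualifier("broken_piece") is not None:
        raise DnaQuineError("lineage fixture: split CDS failed to restore")
    return out


# ---------------------------------------------------------------------------
# BLADE LUT fixture

_SELECTOR_BY_ADDRESS = {"00": "Vika", "01": "B3", "10": "PhiC31", "11": "Bxb1"}


def lut_oracle(selectors: dict, cre: int, flp: int) -> str | None:
    """Analytic oracle, independent of the simulator: the (cre, flp) input
    addresses cell 'cf'; its GFP is expressed iff the selector bit for that
    address is set.  ``selectors`` maps address '00'/'01'/'10'/'11' to 0/1."""
    address = f"{cre}{flp}"
    return f"GFP{address}" if selectors.get(address) else None


def make_blade_lut(seed: int) -> DsDna:
    """The linear six-input LUT circuit:

    promoter . loxP . FRT . Z00 . FRT . Z01 . T . loxP . F3 . Z10 . F3 . Z11 . T

    with each cell Zab = [sel_ab . T . sel_ab . GFP_ab CDS . T].  Cre
    excises the loxP-flanked first half (cells 00 and 01); FLP excises the
    FRT-flanked Z00 and the F3-flanked Z10, so the addressed cell is Z00
    (no signal), Z01 (FLP), Z10 (Cre) or Z11 (Cre+FLP).  A selector input
    excises the terminator guarding its cell's GFP.  Serine-integrase
    selectors (PhiC31, Bxb1) use attB/attP pairs and leave attL behind.
    """
    sites = load_recombinase_sites()
    site_texts = []
    for s in sites.values():
        site_texts.append(s.site_seq)
        if s.attP:
            site_texts.extend([s.attP, s.attL, s.attR])
    enzymes = load_enzymes()
    forbidden = site_texts + [e.recognition for e in enzymes.values()]
    rng = random.Random(("blade", seed).__repr__())

    def sel_pair(name):
        s = sites[name]
        if s.is_serine:
            return s.site_seq, s.attP
        return s.site_seq, s.site_seq

    parts: list[tuple[str, Feature | None]] = []
    feats: list[Feature] = []
    pos = 0

    def add(text: str, key: str | None = None, label: str | None = None):
        nonlocal pos
        if key is not None:
            quals = (("label", label),) if label else ()
            feats.append(Feature(key, Location.single(pos, pos + len(text), "+"), quals))
        parts.append((text, None))
        pos += len(text)

    def spacer(n=12):
        add(_filler(rng, n, forbidden))

    def terminator(tag):
        add(_filler(rng, 30, forbidden), key="terminator", label=tag)

    def cell(address):
        s1, s2 = sel_pair(_SELECTOR_BY_ADDRESS[address])
        add(s1)
        spacer(6)
        terminator(f"T-guard-{address}")
        spacer(6)
        add(s2)
        spacer(6)
        add(_filler(rng, 60, forbidden), key="CDS", label=f"GFP{address}")
        spacer(6)
        terminator(f"T-stop-{address}")

    loxp = sites["Cre"].site_seq
    frt = sites["FLP"].site_seq
    f3 = sites["FLP_F3"].site_seq

    spacer(20)
    add(_filler(rng, 40, forbidden), key="promoter", label="P-circuit")
    spacer(8)
    add(loxp)
    spacer(8)
    add(frt)
    spacer(6)
    cell("00")
    spacer(6)
    add(frt)
    spacer(6)
    cell("01")
    spacer(6)
    terminator("T-half1")
    spacer(8)
    add(loxp)
    spacer(8)
    add(f3)
    spacer(6)
    cell("10")
    spacer(6)
    add(f3)
    spacer(6)
    cell("11")
    spacer(6)
    terminator("T-half2")
    spacer(20)

    seq = "".join(t for t, _ in parts)
    # construction-time guarantees: every site text occurs exactly as designed
    expected = {loxp: 2, frt: 2, f3: 2}
    for name in ("Vika", "B3"):
        expected[sites[name].site_seq] = 2
    for name in ("PhiC31", "Bxb1"):
        expected[sites[name].site_seq] = 1
        expected[sites[name].attP] = 1
    for text, n in expected.items():
        if _count_both_strands(seq, text) != n:
            raise DnaQuineError("LUT fixture: unexpected site count")
    return from_sequence(seq, LINEAR, name="pLUT-circuit", features=feats)
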