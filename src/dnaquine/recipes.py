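"""Cloning protocols composed from the structural primitives.

Each recipe is a composition of the recorded operations (search, crop,
modify ends, cut, flip, join, direct edits), so a recipe's product carries
the primitive-level construction history and is fully quinable:

* PCR: search both primers' 3' annealing regions, crop the flanked span,
  restore the full primer sequences by end modification.
* Restriction digestion: find every cut site, cut once with all of them.
* Ligation: join, grouped under a "ligation" process.
* Gibson assembly: chew back each junction's shared terminal text into
  complementary long sticky ends (modify ends), then join.
* Site-specific recombination: deletion = cut + join, inversion = cut +
  flip + join, applied innermost-pair-first until quiescent; serine
  integrase sites are rewritten to their attL/attR hybrids (one-shot).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

from . import provenance
from .annotate import RESpec, find_re_sites, search_sequence
from .errors import AssemblyError, CircuitError, PrimerError
from .model import CIRCULAR, LINEAR, DsDna, Feature, reverse_complement
from .topology import CutSpec, EndModification, cut, flip, join, modify_ends, crop
from .annotate import edit_sequence


@dataclass(frozen=True)
class Primer:
    """An oligo: the 3'-terminal ``anneal_length`` nucleotides anneal to the
    template; everything 5' of that is a tail appended to the product."""

    seq: str
    anneal_length: int = 18

    def __post_init__(self):
        if not (0 < self.anneal_length <= len(self.seq)):
            raise PrimerError(
                f"anneal_length {self.anneal_length} invalid for a "
                f"{len(self.seq)}-nt primer"
            )

    @property
    def anneal_region(self) -> str:
        return self.seq[-self.anneal_length :].upper()

    @property
    def tail(self) -> str:
        return self.seq[: -self.anneal_length].upper()


def _unique_match(matches, primer_name, strand):
    if not matches:
        raise PrimerError(f"{primer_name} primer does not anneal ({strand} strand)")
    if len(matches) > 1:
        raise PrimerError(
            f"{primer_name} primer anneals at {len(matches)} positions (ambiguous)"
        )
    return matches[0]


def simulate_pcr(template: DsDna, fwd: Primer, rev: Primer, name: str | None = None) -> DsDna:
    """Amplify the template span between the two primer annealing sites.

    The forward primer's annealing region must occur exactly once on the top
    strand and the reverse primer's exactly once on the bottom strand; on a
    linear template the forward site must lie 5' of the reverse site.  The
    product is blunt, fully double-stranded, with both tails appended.
    """
    f = _unique_match(
        search_sequence(template, fwd.anneal_region, strand="+"), "forward", "+"
    )
    r = _unique_match(
        search_sequence(template, rev.anneal_region, strand="-"), "reverse", "-"
    )
    L = len(template.seq)
    fs, re_ = f.start, r.end
    if not template.is_circular and fs >= re_:
        raise PrimerError(
            "primer orientation is wrong: the forward site must lie 5' of the "
            "reverse site on a linear template"
        )
    if template.is_circular and re_ % L == fs:
        raise PrimerError("primer sites coincide; nothing to amplify")
    product = crop(template, CutSpec(fs, fs), CutSpec(re_ % L if template.is_circular else re_,
                                                      re_ % L if template.is_circular else re_))
    mods = []
    if fwd.tail:
        mods.append(EndModification("left", "extend", "top", seq=fwd.tail))
        mods.append(EndModification("left", "extend", "bottom", seq=reverse_complement(fwd.tail)))
    if rev.tail:
        mods.append(EndModification("right", "extend", "top", seq=reverse_complement(rev.tail)))
        mods.append(EndModification("right", "extend", "bottom", seq=rev.tail))
    if mods:
        product = modify_ends(product, *mods)
    product.name = name or f"{template.name}_pcr"
    return product


def load_enzymes() -> dict[str, RESpec]:
    """Bundled restriction enzyme definitions."""
    text = importlib.resources.files("dnaquine.data").joinpath("enzymes.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: RESpec(name, d["recognition"], d["top_offset"], d["bottom_offset"])
        for name, d in raw.items()
    }


def digest(dna: DsDna, *enzymes: RESpec) -> list[DsDna]:
    """Find every site of every enzyme, then cut once with all of them."""
    if not enzymes:
        raise AssemblyError("no enzymes given")
    all_cuts: list[CutSpec] = []
    for enz in enzymes:
        all_cuts.extend(find_re_sites(dna, enz))
    if not all_cuts:
        names = ", ".join(e.name for e in enzymes)
        raise AssemblyError(f"no recognition site in {dna.name!r} for: {names}")
    return cut(dna, *sorted(all_cuts, key=lambda c: (c.top_cut, c.bottom_cut)))


def ligate(fragments, result_topology: str = CIRCULAR, name: str | None = None) -> DsDna:
    """Join fragments with compatible ends (sticky or blunt), recorded under
    a 'ligation' process."""
    with provenance.set_process("ligation", ""):
        return join(fragments, result_topology, name)


def gibson_assembly(
    fragments,
    min_overlap: int = 15,
    result_topology: str = CIRCULAR,
    name: str | None = None,
) -> DsDna:
    """Overlap assembly: every junction's shared terminal text (upstream
    3' end == downstream 5' start, >= min_overlap) is chewed into
    complementary sticky ends and the fragments are joined.  Product length
    is sum(fragments) - sum(overlaps)."""
    frags = list(fragments)
    if len(frags) < 2:
        raise AssemblyError("Gibson assembly needs at least two fragments")
    n = len(frags)
    n_junctions = n if result_topology == CIRCULAR else n - 1
    overlaps: list[int] = []
    for i in range(n_junctions):
        up, down = frags[i], frags[(i + 1) % n]
        limit = min(len(up.seq), len(down.seq)) - 1
        best = 0
        for k in range(1, limit + 1):
            if up.seq[-k:] == down.seq[:k]:
                best = k
        if best < min_overlap:
            raise AssemblyError(
                f"junction {i} ({up.name!r} -> {down.name!r}): best overlap is "
                f"{best} nt, below the minimum of {min_overlap}"
            )
        overlaps.append(best)
    trimmed = []
    for i, frag in enumerate(frags):
        mods = []
        if i < n_junctions:
            mods.append(EndModification("right", "trim", "top", length=overlaps[i]))
        jprev = (i - 1) % n
        if (i > 0 or result_topology == CIRCULAR) and jprev < n_junctions:
            mods.append(EndModification("left", "trim", "bottom", length=overlaps[jprev]))
        trimmed.append(modify_ends(frag, *mods) if mods else frag)
    return join(trimmed, result_topology, name or f"{frags[0].name}_gibson")


# ---------------------------------------------------------------------------
# site-specific recombination

@dataclass(frozen=True)
class RecombinaseSiteSpec:
    """One recombinase target family.

    Tyrosine recombinases (Cre, FLP, Vika, B3) regenerate their sites, so
    ``site_seq`` is both substrate and product.  Serine integrases (PhiC31,
    Bxb1) recombine attB x attP into the inert hybrids attL/attR, making the
    reaction one-shot; ``site_seq`` holds attB and ``attP``/``attL``/``attR``
    the remaining texts (all equal length here by construction).
    """

    family: str
    mechanism: str  # "tyrosine" | "serine_integrase"
    site_seq: str
    attP: str = ""
    attL: str = ""
    attR: str = ""

    @property
    def is_serine(self) -> bool:
        return self.mechanism == "serine_integrase"


def load_recombinase_sites() -> dict[str, RecombinaseSiteSpec]:
    text = (
        importlib.resources.files("dnaquine.data")
        .joinpath("recombinase_sites.yaml")
        .read_text()
    )
    raw = yaml.safe_load(text)
    out = {}
    for name, d in raw.items():
        if d["mechanism"] == "serine_integrase":
            out[name] = RecombinaseSiteSpec(
                d["family"], d["mechanism"], d["attB"], d["attP"], d["attL"], d["attR"]
            )
        else:
            out[name] = RecombinaseSiteSpec(d["family"], d["mechanism"], d["site"])
    return out


def _find_sites(dna: DsDna, text: str):
    return search_sequence(dna, text, strand="both")


def _candidate_pairs(dna: DsDna, spec: RecombinaseSiteSpec):
    """Reaction candidates as (gap, site_i, site_j, kind) with site_i left of
    site_j; innermost (smallest inner gap) first."""
    if spec.is_serine:
        b_sites = _find_sites(dna, spec.site_seq)
        p_sites = _find_sites(dna, spec.attP)
        pools = [(b, p) for b in b_sites for p in p_sites]
        pairs = []
        for a, b in pools:
            pairs.append((a, b) if a.start <= b.start else (b, a))
    else:
        sites = _find_sites(dna, spec.site_seq)
        pairs = [(a, b) for i, a in enumerate(sites) for b in sites[i + 1 :]]
    out = []
    for a, b in pairs:
        if a.end > b.start:  # overlapping sites never react
            continue
        # the in-between segment [a.end, b.start) is the canonical substrate;
        # on circular molecules the wrap-around segment is the complement and
        # the choice only rotates which product is called "main"
        gap = b.start - a.end
        kind = "excision" if a.strand == b.strand else "inversion"
        out.append((gap, a, b, kind))
    out.sort(key=lambda t: (t[0], t[1].start))
    return out


def _rewrite_site(dna: DsDna, start: int, text: str, strand: str) -> DsDna:
    new = text if strand == "+" else reverse_complement(text)
    return edit_sequence(dna, (start, start + len(new)), new)


def apply_recombinase(dna: DsDna, spec: RecombinaseSiteSpec):
    """Apply one recombinase family until quiescent.

    Same-orientation pair: excision — the main molecule is rejoined around
    one site; the excised circle (carrying the other site) is returned as a
    byproduct and does not react further.  Opposite orientation: inversion
    of the sandwiched segment, each position pair reacted at most once
    (tyrosine inversion is an equilibrium; one pass is the deterministic
    desk model).  Serine-integrase reactions rewrite the participating sites
    to attL (main) / attR (byproduct or downstream site), so they cannot
    re-react.  Fewer than two sites: no-op (the searches are still
    recorded).

    Returns (main molecule, list of excised circular byproducts).
    """
    main = dna
    byproducts: list[DsDna] = []
    done_inversions: set[tuple[int, int]] = set()
    while True:
        cands = _candidate_pairs(main, spec)
        cands = [
            c for c in cands
            if not (c[3] == "inversion" and (c[1].start, c[2].start) in done_inversions)
        ]
        if not cands:
            break
        _gap, a, b, kind = cands[0]
        if kind == "excision":
            if main.is_circular:
                frags = cut(main, CutSpec(a.start, a.start), CutSpec(b.start, b.start))
                excised, keeper = frags[0], frags[1]
                circle = join([excised], CIRCULAR, name=f"{main.name}_excised")
                main = join([keeper], CIRCULAR, name=main.name)
                site_pos_main = 0
            else:
                frags = cut(main, CutSpec(a.start, a.start), CutSpec(b.start, b.start))
                circle = join([frags[1]], CIRCULAR, name=f"{main.name}_excised")
                main = join([frags[0], frags[2]], LINEAR, name=main.name)
                site_pos_main = a.start
            if spec.is_serine:
                main = _rewrite_site(main, site_pos_main, spec.attL, b.strand)
                circle = _rewrite_site(circle, 0, spec.attR, a.strand)
            byproducts.append(circle)
        else:  # inversion
            frags = cut(main, CutSpec(a.end, a.end), CutSpec(b.start, b.start))
            if main.is_circular:
                middle, keeper = frags[0], frags[1]
                main = join([flip(middle), keeper], CIRCULAR, name=main.name)
            else:
                main = join([frags[0], flip(frags[1]), frags[2]], LINEAR, name=main.name)
            done_inversions.add((a.start, b.start))
            if spec.is_serine:
                main = _serine_rewrite_inversion(main, spec, a, b)
    return main, byproducts


def _serine_rewrite_inversion(main: DsDna, spec: RecombinaseSiteSpec, a, b) -> DsDna:
    """After an inversion, replace the attB/attP pair with attL/attR.  The
    flanking sites did not move (the cuts were placed at a.end and b.start),
    so their positions are still a.start and b.start on linear molecules;
    on circular molecules the product was rotated by the cut, so the sites
    are re-located by text search."""
    if not main.is_circular:
        first = _rewrite_site(main, a.start, spec.attL, a.strand)
        return _rewrite_site(first, b.start, spec.attR, b.strand)
    for text, repl in ((spec.site_seq, spec.attL), (spec.attP, spec.attR)):
        hits = search_sequence(main, text, strand="both")
        if hits:
            main = _rewrite_site(main, hits[0].start, repl, hits[0].strand)
    return main


# ---------------------------------------------------------------------------
# transcription-unit expression call and the BLADE LUT driver

def call_expression(dna: DsDna):
    """The CDS expressed from the molecule's single promoter, or None.

    Scans downstream of the promoter in its orientation (wrapping at most
    one full turn on circular molecules): the first same-orientation CDS
    encountered before any same-orientation terminator is expressed; a
    terminator first means no expression.  Opposite-orientation features are
    transparent.
    """
    promoters = [f for f in dna.features if f.key == "promoter"]
    if len(promoters) != 1:
        raise CircuitError(
            f"expression call needs exactly one promoter feature, found {len(promoters)}"
        )
    prom = promoters[0]
    L = len(dna.seq)
    sigma = prom.location.strand
    origin = prom.location.end if sigma == "+" else prom.location.start
    candidates = []
    for f in dna.features:
        if f.key not in ("CDS", "terminator"):
            continue
        if sigma == "+":
            d = f.location.start - origin
        else:
            d = origin - f.location.end
        if dna.is_circular:
            d %= L
        elif d < 0:
            continue
        candidates.append((d, f))
    for _d, f in sorted(candidates, key=lambda t: t[0]):
        if f.location.strand != sigma:
            continue
        if f.key == "terminator":
            return None
        return f
    return None


BLADE_ORDER = ("Vika", "B3", "PhiC31", "Bxb1", "Cre", "FLP")
_INPUT_ALIASES = {"Vica": "Vika"}


def simulate_blade(circuit: DsDna, inputs):
    """Apply the input recombinases to the LUT circuit (fixed order: Vika,
    B3, PhiC31, Bxb1, Cre, FLP — the outcome is order-independent for the
    LUT fixture, which is asserted by tests), each to quiescence, then call
    expression.  FLP acts on both of its heterospecific families (FRT and
    F3).  Returns (final molecule, expressed CDS feature or None)."""
    sites = load_recombinase_sites()
    chosen = set()
    for raw in inputs:
        name = _INPUT_ALIASES.get(raw, raw)
        if name not in BLADE_ORDER:
            raise CircuitError(f"unknown recombinase input {raw!r}")
        chosen.add(name)
    mol = circuit
    for name in BLADE_ORDER:
        if name not in chosen:
            continue
        specs = [sites[name]] if name != "FLP" else [sites["FLP"], sites["FLP_F3"]]
        for spec in specs:
            mol, _by = apply_recombinase(mol, spec)
    return mol, call_expression(mol)
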