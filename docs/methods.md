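# Methods

## The dsDNA model and its conventions

A molecule stores only its top strand; coordinates are 0-based, half-open,
top-strand (GenBank serialization converts to 1-based inclusive, with
`complement()` / `join()` forms). Single-stranded protrusions of the
*bottom* strand at an end (a 5′ overhang on the right, a 3′ overhang on the
left) are not part of the stored sequence — they live in the end
structures, whose overhang text is always written 5'→3' along the
protruding strand. Two consequences the arithmetic relies on:

- **Annealing test.** Two ends ligate iff they are both blunt, or have the
  same overhang class and their texts are exact reverse complements. An
  `N` in an overhang never anneals (conservative model; `N` is allowed in
  duplex sequence).
- **Conservation.** At any ligatable junction exactly one partner carries
  the annealed overhang on its top strand, so the product top strand is the
  plain concatenation of fragment top strands, and cutting conserves the
  parent's top-strand nucleotide count exactly. This makes the cut/join
  inverse and the rotation-invariance of circular cutting checkable as
  string identities, which the randomized suites do over 100 seeds each.

Cut semantics: a strand is severed between positions `p−1` and `p`; both
positions of a `CutSpec` are top-strand coordinates. Cuts through
single-stranded end regions and cuts whose overhang regions overlap are
rejected; on circular molecules the bottom position is interpreted modulo
length, linearized next to its top position.

End modification is implemented once for the left end (extend/trim on
either strand, with complementarity checked when an extension fills an
existing overhang) and mirrored to the right end through a structural flip,
which keeps the two sides provably symmetric (a unit test asserts the
mirror identity). A trim that removes top-strand positions clips
overlapping features into broken pieces; this is what lets Gibson-style
end-chewing keep track of a CDS that straddles a junction.

## Broken features and restoration

A piece of a split feature carries `original_id` (the parent feature's
stable id), `original_span` (its half-open offset interval within the
parent, measured along the feature's own strand), `original_len`,
`original_checksum` (8-hex digest of the parent's own-strand sequence at
break time) and a cosmetic `broken_piece = k/of/N`. On every join,
molecule-adjacent pieces with contiguous spans merge (including across the
origin of a circular product); a merged piece covering `0..original_len`
whose reconstituted sequence matches the checksum is replaced by the
restored feature with the original key, qualifiers and feature id. Because
`feature_id` is a content hash fixed at creation and preserved through
inheritance, two molecules that inherited the same feature from a common
source carry the same id — restoration therefore works for pieces arriving
from *different* molecules, which is exactly the two-fragment re-assembly
scenario the lineage fixture exercises.

## Histories, the script dialect, and the quine

Every public operation records an `OperationRecord`;
`step_id = SHA-256("qrs1" | op | canonical-JSON args | sorted parents)[:16]`.
Canonical JSON sorts keys and renders molecule inputs as
`@<step_id>#<output-index>` references. A product's history is the
order-preserving, de-duplicated union of its parents' histories plus its
own record, so shared ancestors appear once and histories are always
topologically ordered and closed under parents (validated on read).
Searches record into the searched molecule's history in place — they are
part of the narrative (sites are *found*) — which is why the cloning
demonstration counts 11 operational records rather than 5.

The quine is expressed in a neutral line-oriented dialect (`#qrs v1`,
`names = op {json}`, `!` for no-output searches) rather than host-language
source: replay interprets each command through the same public operations,
so rebuilt step ids must equal the scripted names (asserted during replay),
and `generate_quine ∘ replay` is a byte-level fixed point. Source records
embed their sequence and features inline, so a script needs no external
files. Process annotations from `set_process` travel inside the canonical
arguments (hence inside the step id) and feed the methods-text export.

GenBank embedding: one percent-encoded qualifier per record
(`building_history_<k>`) on a full-span `source` feature, plus end
structures and the product's own origin reference. The payload alphabet
excludes spaces; Biopython's line wrapping re-joins wrapped qualifier
values with spaces, so stripping spaces on read makes the round trip
lossless (verified byte-for-byte). The LOCUS date is written as a fixed
stamp so that output is a pure function of content; equality checks in the
tests additionally ignore any date token.

## Recipes

- **PCR** requires the forward 3′ annealing region (default 18 nt, exact
  match) to occur once on the top strand and the reverse once on the
  bottom; the product is `fwd tail + span + rc(rev tail)`, built as
  search, search, crop, one modify-ends call (both tails, both strands).
- **Digestion** is find-sites per enzyme then one cut with all sites;
  enzyme rules (IUPAC recognition, top/bottom offsets, Type IIS supported)
  ship in `data/enzymes.yaml`.
- **Gibson assembly** finds each junction's maximal shared terminal text
  (≥ `min_overlap`, default 15 nt), chews the upstream top and downstream
  bottom strands back by that length, and joins; product length is
  Σ fragments − Σ overlaps.
- **Recombination** locates sites by sequence search; a same-orientation
  pair excises (cut at both site starts, rejoin; the excised circle keeps
  one site and is returned as a byproduct, excluded from further reaction —
  modelling dilution of non-replicating circles), an antiparallel pair
  inverts (cut at inner site boundaries, flip, rejoin). Pairs react
  innermost-first; tyrosine inversions are applied once per position pair
  (the physical reaction is an equilibrium; one deterministic pass is the
  desk model). Serine integrases rewrite the participating attB/attP to
  equal-length attL/attR hybrids, making the reaction one-shot.
- **Expression call**: from the molecule's single promoter, scan downstream
  in its orientation (≤ one full turn on circles); the first
  same-orientation CDS before any same-orientation terminator is expressed.

## Synthetic fixtures: what they emulate, and what they do not

All demonstration materials are generated from a seed; identical seeds give
byte-identical fixtures, and screening loops redraw on collision so any
seed is valid. Filler is uniform random ACGT screened (both strands)
against every bundled enzyme recognition and recombinase site.

- *Cloning pair*: ~3.0 kb circular donor (720 nt eGFP-analog CDS flanked by
  unique 18-mers), 5.0 kb circular backbone with single EcoRI and BamHI
  sites 40 nt apart; primer tails are `NNNN + site + anneal`.
- *Lineage*: five ~1 kb roots, four first-generation Gibson products of
  two PCR fragments each (20-nt junction linkers), two second-generation
  products; one of them amplifies the 600-nt Cas9(D10A)-analog CDS as two
  blocks from two different parents with the 20-nt overlap inside the CDS.
  Sizes are deliberately desk-scale: every law being checked (lengths,
  identities, hash equalities) is size-independent.
- *LUT circuit*: a ~1.3 kb linear circuit,
  `promoter · loxP · FRT · Z00 · FRT · Z01 · T · loxP · F3 · Z10 · F3 · Z11 · T`
  with `Zab = sel_ab · T · sel_ab · GFP_ab · T`. The circuit is
  excision-only (selector sites ungate their cell's GFP; Cre/FLP address
  the cell), which keeps all 64 outcomes analytically derivable by the
  independent oracle `expressed ⇔ selector bit of the (Cre,FLP)-addressed
  cell`; inversion logic is exercised separately by unit tests (including
  a FLEx-style orientation switch). loxP, FRT and F3 are the canonical
  34-bp site texts; the vox, B3RT and att sites are synthetic stand-ins
  with the same arm/core/arm architecture, declared as such in
  `data/recombinase_sites.yaml`.

What passing these fixtures does **not** show about real data: no
thermodynamics (annealing is exact text equality; primers and overlaps
never mismatch), no enzyme star activity or methylation sensitivity, no
sequence realism in the filler (no promoters, codon structure or GC
constraints), and recombination is deterministic single-molecule logic
rather than a population equilibrium.

## Numerical and design choices

- Hashes are truncated (16 hex for steps and record ids, 8 for features) —
  collision-safe at desk scale, compact inside GenBank qualifiers.
- Fuzzy matching: Hamming for sequence (IUPAC mode only), Levenshtein for
  feature text; both are exact small-scale scans, no heuristics.
- Join is strictly order-respecting; no search over fragment orders or
  orientations. Assembly search is a non-goal.
- Degenerate inputs: empty sequences, cuts at position 0/L of a linear
  molecule, trims past the duplex, joins of circular inputs, and edits out
  of bounds are all rejected with typed errors rather than coerced.
- `record_id` (content identity) covers sequence, topology, ends and
  canonicalized features but not the display name; product names are
  cosmetic.

## Known limitations

- Multi-record GenBank files: only the first record is read (warned).
- A feature lying in a single-stranded end region that is then flipped or
  trimmed away is clipped; ssDNA is not a first-class object.
- Tyrosine-recombinase inversion equilibria are represented by a single
  deterministic pass; repeated `apply_recombinase` calls do not oscillate.
- Histories grow monotonically with every recorded search; no compaction
  or compression of embedded histories is attempted.
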