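# dnaquine

Simulated molecular cloning on annotated double-stranded DNA, with every
operation recorded into a content-addressed construction history that is
embedded in the output GenBank file — and from which the file can
regenerate the very script that built it (a *quine*).

## Who this is for

Molecular biologists and synthetic-biology tool builders who want DNA
construction protocols that are **executable and reproducible**: instead of
describing a cloning in prose, you script it from a small operational
algebra, and every product you write out as GenBank carries its complete,
verifiable build recipe. Files remain perfectly ordinary GenBank records to
every other tool — the history rides along as qualifiers on a full-span
`source` feature.

## The model

A molecule is a `DsDna`: a top-strand sequence (5'→3', 0-based half-open
coordinates), a topology (linear/circular), two end structures for linear
molecules (blunt, 5′ overhang or 3′ overhang, each overhang written 5'→3'
along the protruding strand), a set of strand-aware features, and a
history. Four structural primitives generate all standard cloning
operations:

- **cut** — sever both strands at a dual-position cut `(top, bottom)`;
  `top == bottom` is blunt, otherwise a sticky end. EcoRI (G^AATTC) at
  site position *s* is `CutSpec(s+1, s+5)`.
- **flip** — reverse complement; features remap as `[s,e) → [L−e, L−s)`
  with strand toggled.
- **join** — concatenate fragments whose junction ends are blunt/blunt or
  carry reverse-complementary overhangs of the same class.
- **modify ends** — add or trim single-stranded sequence on either strand
  of either end (this is how long Gibson-style overlaps become sticky
  ends).

Two search functions (sequence by IUPAC/regex/Hamming; features by
key/qualifier with exact, regex or Levenshtein matching) and two direct
edit functions (sequence replacement, feature create/remove/update)
complete the algebra. Recipes — PCR, restriction digestion, ligation,
Gibson assembly, site-specific recombination (Cre/FLP-style excision and
inversion, serine-integrase attB×attP → attL/attR) — are compositions of
these primitives, so their products inherit primitive-level histories.

Every operation record's identity is
`step_id = SHA-256(op, canonical JSON args, sorted parent ids)[:16]`, so
identical operations on identical inputs always hash identically: replaying
a regenerated script rebuilds the same step ids, and descendants inherit
the union of their parents' histories. Features split by an operation carry
`broken_piece` / `original_span` / `original_id` qualifiers and are
restored — same key, qualifiers and feature id — when a join reconstitutes
the original sequence, even across molecules.

## Worked example

```python
import dnaquine as dq
from dnaquine import fixtures as fx

demo = fx.run_cloning_demo(seed=1)      # synthetic donor + backbone
plasmid = demo["plasmid"]               # eGFP-analog cassette cloned via
                                        # PCR -> EcoRI/BamHI -> ligation
steps = [r.op_name for r in plasmid.history if r.op_name != "source"]
print(len(plasmid.seq), plasmid.topology)
print(len(steps), steps)
```

prints

```
5776 circular
11 ['search_sequence', 'search_sequence', 'crop', 'modify_ends',
    'find_re_sites', 'find_re_sites', 'cut',
    'find_re_sites', 'find_re_sites', 'cut', 'join']
```

— the classic "search both primers, crop, restore the tails, find both
enzymes' sites on product and backbone, double-digest both, ligate"
protocol in 11 recorded operational steps (the two `source` loads are the
input materials, not operations). Writing and reading the product is
lossless and self-reproducing:

```python
dq.write_genbank(plasmid, "product.gbk")
script = dq.generate_quine(dq.read_genbank("product.gbk"))
env = dq.replay(script)                 # rebuilds every molecule
```

`replay` returns molecules whose sequences, features and step ids equal the
originals, and regenerating the script from a replayed product is
byte-identical — the quine fixed point.

A command-line interface mirrors the library
(`dnaquine pcr | digest | ligate | gibson | recombine | blade | fixtures |
quine | replay | show`).

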