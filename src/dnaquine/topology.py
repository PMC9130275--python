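"""The four basic structural operations — cut, flip, join, modify ends —
plus crop, with feature inheritance, broken-feature marking and restoration.

Cut semantics: a CutSpec severs the top strand between ``top_cut - 1`` and
``top_cut`` and the bottom strand between ``bottom_cut - 1`` and
``bottom_cut``; both positions are top-strand coordinates.  EcoRI
(G^AATTC) at site position ``s`` therefore cuts at ``(s + 1, s + 5)``.

Broken-feature bookkeeping: when an operation splits a feature, each piece
carries qualifiers

* ``broken_piece``       "k/of/N" (cosmetic ordering among sibling pieces)
* ``original_id``        the parent feature's feature_id
* ``original_span``      "u..v": the piece's half-open offset interval within
                         the parent feature, measured 5'->3' along the
                         feature's own strand
* ``original_len``       the parent feature's total length
* ``original_checksum``  8-hex digest of the parent feature's own-strand
                         sequence at break time

Joining re-merges pieces whose spans are contiguous and adjacent in molecule
order; a merged piece covering the full span whose reconstituted sequence
matches ``original_checksum`` is replaced by the restored feature (same key,
qualifiers and feature_id), even when the pieces came from different
molecules.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

from . import provenance
from .errors import (
    CutError,
    EndModificationError,
    IncompatibleEndsError,
    TopologyError,
)
from .model import (
    BLUNT,
    BLUNT_END,
    CIRCULAR,
    FIVE_PRIME,
    LINEAR,
    THREE_PRIME,
    DsDna,
    EndStructure,
    Feature,
    Location,
    feature_own_sequence,
    normalize_sequence,
    reverse_complement,
    subsequence,
)

BROKEN_QUALIFIERS = (
    "broken_piece",
    "original_id",
    "original_span",
    "original_len",
    "original_checksum",
)


@dataclass(frozen=True)
class CutSpec:
    """A dual-strand cut position pair; equal positions mean a blunt cut."""

    top_cut: int
    bottom_cut: int
    label: str | None = None

    @property
    def overhang_length(self) -> int:
        return abs(self.top_cut - self.bottom_cut)

    def to_obj(self):
        return [self.top_cut, self.bottom_cut, self.label]

    @staticmethod
    def from_obj(obj) -> "CutSpec":
        return CutSpec(int(obj[0]), int(obj[1]), obj[2])


@dataclass(frozen=True)
class EndModification:
    """One single-stranded end change.

    mode "extend": add ``seq`` (5'->3' along the chosen strand) to the
    chosen end of the chosen strand.  mode "trim": remove ``length``
    nucleotides from that strand at that end.
    """

    side: str  # left | right
    mode: str  # extend | trim
    strand: str  # top | bottom
    seq: str = ""
    length: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right") or self.strand not in ("top", "bottom"):
            raise EndModificationError(f"bad side/strand {self.side}/{self.strand}")
        if self.mode == "extend":
            if not self.seq or self.length:
                raise EndModificationError("extend requires seq and no length")
        elif self.mode == "trim":
            if self.seq or self.length <= 0:
                raise EndModificationError("trim requires a positive length and no seq")
        else:
            raise EndModificationError(f"bad mode {self.mode}")

    def to_obj(self):
        return [self.side, self.mode, self.strand, self.seq if self.mode == "extend" else self.length]

    @staticmethod
    def from_obj(obj) -> "EndModification":
        side, mode, strand, value = obj
        if mode == "extend":
            return EndModification(side, mode, strand, seq=value)
        return EndModification(side, mode, strand, length=int(value))


# ---------------------------------------------------------------------------
# feature-sense coordinate helpers

def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:8]


def _linearized_segments(loc: Location, length: int):
    """Segments with origin-spanning locations unwrapped into one interval
    whose end may exceed the molecule length."""
    if loc.crosses_origin:
        s, e = loc.linearized(length)
        return ((s, e),)
    return loc.segments


def _fsense_map(segments, strand):
    """[(segment, base offset)] where the base offset is the feature-sense
    offset at the segment boundary nearest the feature's 5' end."""
    lens = [e - s for s, e in segments]
    out = []
    if strand != "-":
        off = 0
        for seg, ln in zip(segments, lens):
            out.append((seg, off))
            off += ln
    else:
        off = 0
        tmp = []
        for seg, ln in zip(reversed(segments), reversed(lens)):
            tmp.append((seg, off))
            off += ln
        out = list(reversed(tmp))
    return out


def _original_info(dna: DsDna, feat: Feature):
    """(original_id, original_len, checksum, base_offset) for breaking a
    feature of ``dna`` — composes with existing broken-piece qualifiers."""
    oid = feat.qualifier("original_id")
    if oid is not None:
        span = feat.qualifier("original_span") or "0..0"
        p = int(span.split("..")[0])
        return (
            oid,
            int(feat.qualifier("original_len") or feat.location.length),
            feat.qualifier("original_checksum") or "",
            p,
        )
    return (
        feat.feature_id,
        feat.location.length,
        _checksum(feature_own_sequence(dna, feat)),
        0,
    )


def _piece(feat: Feature, info, start: int, end: int, u: int, v: int) -> Feature:
    oid, olen, chk, base = info
    u, v = base + u, base + v
    quals = [(k, val) for k, val in feat.qualifiers if k not in BROKEN_QUALIFIERS]
    quals += [
        ("broken_piece", "1/of/1"),
        ("original_id", oid),
        ("original_span", f"{u}..{v}"),
        ("original_len", str(olen)),
        ("original_checksum", chk),
    ]
    loc = Location.single(start, end, feat.location.strand)
    fid = hashlib.sha256(f"{oid}|{u}|{v}|{start}|{end}".encode()).hexdigest()[:8]
    return Feature(feat.key, loc, tuple(quals), fid)


def _renumber(features: list[Feature]) -> list[Feature]:
    """Refresh the cosmetic k/of/N numbering among sibling broken pieces."""
    groups: dict[str, list[int]] = {}
    for i, f in enumerate(features):
        oid = f.qualifier("original_id")
        if oid is not None:
            groups.setdefault(oid, []).append(i)
    out = list(features)
    for oid, idxs in groups.items():
        idxs.sort(key=lambda i: int((features[i].qualifier("original_span") or "0..0").split("..")[0]))
        n = len(idxs)
        for k, i in enumerate(idxs, start=1):
            out[i] = out[i].with_qualifiers({"broken_piece": f"{k}/of/{n}"})
    return out


def _extract_window(dna: DsDna, w0: int, w1: int) -> list[Feature]:
    """Features of ``dna`` falling in the (linearized) window [w0, w1),
    re-based to window coordinates; partial overlaps become broken pieces.
    On circular molecules the feature is tried at shifts of +-L so that
    windows wrapping the origin are handled."""
    L = len(dna.seq)
    out: list[Feature] = []
    shifts = (-L, 0, L) if dna.is_circular else (0,)
    for feat in dna.features:
        segments = _linearized_segments(feat.location, L)
        fmap = _fsense_map(segments, feat.location.strand)
        for k in shifts:
            hits = []
            for (s, e), beta in fmap:
                a, b = max(s + k, w0), min(e + k, w1)
                if a < b:
                    hits.append(((s, e), beta, a, b))
            if not hits:
                continue
            covered = sum(b - a for (_, _, a, b) in hits)
            if covered == feat.location.length and len(hits) == len(fmap):
                newsegs = tuple((a - w0, b - w0) for (_, _, a, b) in hits)
                out.append(
                    replace(feat, location=Location(newsegs, feat.location.strand))
                )
            else:
                info = _original_info(dna, feat)
                for (s, e), beta, a, b in hits:
                    if feat.location.strand == "-":
                        u, v = beta + (e + k - b), beta + (e + k - a)
                    else:
                        u, v = beta + (a - (s + k)), beta + (b - (s + k))
                    out.append(_piece(feat, info, a - w0, b - w0, u, v))
    return _renumber(out)


# ---------------------------------------------------------------------------
# restoration

def _restore_features(features: list[Feature], seq: str, topology: str) -> list[Feature]:
    probe = DsDna(name="_probe", seq=seq, topology=topology)

    def own_seq(loc: Location) -> str:
        return feature_own_sequence(probe, replace_loc_feature(loc))

    def replace_loc_feature(loc):
        return Feature("_", loc)

    mergeable: dict[tuple[str, str], list[Feature]] = {}
    passthrough: list[Feature] = []
    for f in features:
        oid = f.qualifier("original_id")
        if oid is not None and not f.location.crosses_origin:
            mergeable.setdefault((oid, f.location.strand), []).append(f)
        else:
            passthrough.append(f)

    restored_out: list[Feature] = []
    L = len(seq)
    for (oid, strand), pieces in mergeable.items():
        pieces = sorted(pieces, key=lambda f: f.location.start)
        pieces = _merge_run(pieces, strand)
        if topology == CIRCULAR and len(pieces) >= 2:
            first, last = pieces[0], pieces[-1]
            if last.location.end == L and first.location.start == 0:
                merged = _try_merge(last, first, strand, wrap_length=L)
                if merged is not None:
                    pieces = pieces[1:-1] + [merged]
        final = []
        for p in pieces:
            span = p.qualifier("original_span")
            olen = int(p.qualifier("original_len") or -1)
            u, v = (int(x) for x in span.split(".."))
            if (u, v) == (0, olen):
                chk = p.qualifier("original_checksum") or ""
                if chk and _checksum(own_seq(p.location)) == chk:
                    final.append(
                        replace(p.without_qualifiers(BROKEN_QUALIFIERS), feature_id=oid)
                    )
                    continue
            final.append(p)
        restored_out.extend(final)
    return _renumber(passthrough + restored_out)


def _merge_run(pieces: list[Feature], strand: str) -> list[Feature]:
    changed = True
    while changed and len(pieces) > 1:
        changed = False
        for i in range(len(pieces) - 1):
            merged = _try_merge(pieces[i], pieces[i + 1], strand)
            if merged is not None:
                pieces = pieces[:i] + [merged] + pieces[i + 2 :]
                changed = True
                break
    return pieces


def _try_merge(a: Feature, b: Feature, strand: str, wrap_length: int | None = None) -> Feature | None:
    """Merge molecule-adjacent pieces a (left) and b (right) when their
    original-span intervals are contiguous in feature order."""
    la, lb = a.location, b.location
    if wrap_length is None:
        if la.end != lb.start:
            return None
    else:
        if not (la.end == wrap_length and lb.start == 0):
            return None
    ua, va = (int(x) for x in a.qualifier("original_span").split(".."))
    ub, vb = (int(x) for x in b.qualifier("original_span").split(".."))
    if strand == "-":
        if ua != vb:
            return None
        span = f"{ub}..{va}"
    else:
        if va != ub:
            return None
        span = f"{ua}..{vb}"
    if wrap_length is None:
        loc = Location.single(la.start, lb.end, strand)
    else:
        loc = Location(((la.start, wrap_length), (0, lb.end)), strand, crosses_origin=True)
    merged = a.with_qualifiers({"original_span": span})
    fid = hashlib.sha256(
        f"{a.qualifier('original_id')}|{span}|{la.start}|{lb.end}".encode()
    ).hexdigest()[:8]
    return replace(merged, location=loc, feature_id=fid)


# ---------------------------------------------------------------------------
# structural cut / crop

def _duplex_bounds(dna: DsDna) -> tuple[int, int]:
    """Top-coordinate interval over which both strands are present."""
    L = len(dna.seq)
    if dna.is_circular:
        return 0, L
    x = dna.left_end.length if dna.left_end.kind == FIVE_PRIME else 0
    y = L - dna.right_end.length if dna.right_end.kind == THREE_PRIME else L
    return x, y


def _near(b: int, t: int, L: int) -> int:
    """Linearize a circular bottom-cut position next to its top-cut."""
    cands = (b, b + L, b - L)
    return min(cands, key=lambda c: abs(c - t))


def _fragment_between(dna: DsDna, c1: tuple[int, int] | None, c2: tuple[int, int] | None,
                      name: str) -> DsDna:
    """Build the fragment whose left boundary is cut c1=(t1,b1) and right
    boundary c2=(t2,b2), positions already linearized (t2 may exceed L on a
    circular parent).  ``None`` means the existing molecule end (linear)."""
    L = len(dna.seq)
    t1, b1 = c1 if c1 is not None else (0, 0)
    t2, b2 = c2 if c2 is not None else (L, L)
    if t2 <= t1:
        raise CutError(f"cuts delimit an empty fragment (top {t1}..{t2})")
    top = subsequence(dna, t1, t2)
    if c1 is None:
        left = dna.left_end
    elif t1 < b1:
        left = EndStructure(FIVE_PRIME, subsequence(dna, t1, b1))
    elif t1 > b1:
        left = EndStructure(THREE_PRIME, reverse_complement(subsequence(dna, b1, t1)))
    else:
        left = BLUNT_END
    if c2 is None:
        right = dna.right_end
    elif b2 < t2:
        right = EndStructure(THREE_PRIME, subsequence(dna, b2, t2))
    elif b2 > t2:
        right = EndStructure(FIVE_PRIME, reverse_complement(subsequence(dna, t2, b2)))
    else:
        right = BLUNT_END
    feats = _extract_window(dna, t1, t2)
    return DsDna(name=name, seq=top, topology=LINEAR, left_end=left, right_end=right,
                 features=feats)


def _prepare_cuts(dna: DsDna, cuts) -> list[tuple[int, int]]:
    if not cuts:
        raise CutError("at least one cut is required")
    L = len(dna.seq)
    x, y = _duplex_bounds(dna)
    prepared = []
    for c in cuts:
        t, b = c.top_cut, c.bottom_cut
        if dna.is_circular:
            t %= L
            b = _near(b % L, t, L)
        else:
            if not (0 < t < L) or not (0 < b < L):
                raise CutError(f"cut ({c.top_cut}, {c.bottom_cut}) out of range for length {L}")
            if min(t, b) < x or max(t, b) > y:
                raise CutError(
                    f"cut ({t}, {b}) lies in a single-stranded end region "
                    f"(duplex is [{x}, {y}))"
                )
        prepared.append((t, b))
    prepared.sort(key=lambda tb: tb[0])
    if len({t for t, _ in prepared}) != len(prepared):
        raise CutError("cut positions are not distinct after normalization")
    # overhang regions may not overlap
    ivs = sorted((min(t, b), max(t, b)) for t, b in prepared)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if e1 > s2:
            raise CutError(f"overlapping overhang regions [{s1},{e1}) and [{s2},{e2})")
    if dna.is_circular and len(ivs) > 1:
        s1, e1 = ivs[0]
        s2, e2 = ivs[-1]
        if e2 - L > s1:
            raise CutError("overlapping overhang regions across the origin")
    return prepared


def _structural_cut(dna: DsDna, cuts) -> list[DsDna]:
    prepared = _prepare_cuts(dna, cuts)
    L = len(dna.seq)
    frags: list[DsDna] = []
    if dna.is_circular:
        n = len(prepared)
        for i, (t1, b1) in enumerate(prepared):
            t2, b2 = prepared[(i + 1) % n]
            if (i + 1) == n:
                t2, b2 = t2 + L, b2 + L
            frags.append(
                _fragment_between(dna, (t1, b1), (t2, b2), f"{dna.name}_f{i}")
            )
    else:
        bounds = [None] + [tuple(p) for p in prepared] + [None]
        for i in range(len(bounds) - 1):
            frags.append(
                _fragment_between(dna, bounds[i], bounds[i + 1], f"{dna.name}_f{i}")
            )
    return frags


# ---------------------------------------------------------------------------
# structural flip

def _bottom_extent(dna: DsDna) -> tuple[int, int]:
    """Interval covered by the bottom strand, in top coordinates (may extend
    past [0, L) where the bottom protrudes)."""
    L = len(dna.seq)
    lo = {FIVE_PRIME: dna.left_end.length, THREE_PRIME: -dna.left_end.length}.get(
        dna.left_end.kind, 0
    )
    hi = L + {FIVE_PRIME: dna.right_end.length, THREE_PRIME: -dna.right_end.length}.get(
        dna.right_end.kind, 0
    )
    return lo, hi


def _structural_flip(dna: DsDna) -> DsDna:
    if dna.is_circular:
        L = len(dna.seq)
        new_seq = reverse_complement(dna.seq)
        feats = []
        for f in dna.features:
            segs = _linearized_segments(f.location, L)
            mapped = []
            for s, e in segs:
                ns, ne = L - e, L - s
                mapped.append((ns, ne))
            mapped.sort()
            strand = "-" if f.location.strand == "+" else "+"
            locs = []
            for ns, ne in mapped:
                locs.append(Location.from_linear(ns % L, (ns % L) + (ne - ns), strand, L))
            if len(mapped) == 1:
                loc = locs[0]
            else:
                allsegs = tuple(seg for lc in locs for seg in lc.segments)
                loc = Location(allsegs, strand, any(lc.crosses_origin for lc in locs))
            feats.append(replace(f, location=loc))
        return DsDna(name=f"{dna.name}_flip", seq=new_seq, topology=CIRCULAR, features=feats)

    L = len(dna.seq)
    lo, hi = _bottom_extent(dna)
    x, y = max(lo, 0), min(hi, L)
    parts = []
    if dna.right_end.kind == FIVE_PRIME:
        parts.append(dna.right_end.overhang_seq)
    parts.append(reverse_complement(dna.seq[x:y]))
    if dna.left_end.kind == THREE_PRIME:
        parts.append(dna.left_end.overhang_seq)
    new_seq = "".join(parts)
    W = hi - lo
    window_feats = _extract_window(dna, lo, hi)
    flipped = []
    for f in window_feats:
        mapped = sorted((W - e, W - s) for s, e in f.location.segments)
        strand = "-" if f.location.strand == "+" else "+"
        flipped.append(
            replace(f, location=Location(tuple(mapped), strand))
        )
    return DsDna(
        name=f"{dna.name}_flip",
        seq=new_seq,
        topology=LINEAR,
        left_end=dna.right_end,
        right_end=dna.left_end,
        features=flipped,
    )


# ---------------------------------------------------------------------------
# structural join

def ends_compatible(a: EndStructure, b: EndStructure) -> bool:
    """Can end ``a`` (right end of the upstream fragment) ligate to end ``b``
    (left end of the downstream fragment)?  Blunt with blunt, or same
    overhang class with reverse-complementary texts; N never anneals."""
    if a.kind == BLUNT and b.kind == BLUNT:
        return True
    if a.kind != b.kind or a.kind == BLUNT:
        return False
    if "N" in a.overhang_seq or "N" in b.overhang_seq:
        return False
    return reverse_complement(a.overhang_seq) == b.overhang_seq


def _structural_join(fragments: list[DsDna], topology: str, name: str) -> DsDna:
    if not fragments:
        raise IncompatibleEndsError("empty fragment list")
    for f in fragments:
        if f.is_circular:
            raise TopologyError(f"cannot join circular molecule {f.name!r}")
    for i in range(len(fragments) - 1):
        a, b = fragments[i], fragments[i + 1]
        if not ends_compatible(a.right_end, b.left_end):
            raise IncompatibleEndsError(
                f"junction {i}: {a.name!r} right end ({a.right_end.describe()}) is "
                f"incompatible with {b.name!r} left end ({b.left_end.describe()})"
            )
    if topology == CIRCULAR:
        a, b = fragments[-1], fragments[0]
        if not ends_compatible(a.right_end, b.left_end):
            raise IncompatibleEndsError(
                f"circular junction: {a.name!r} right end ({a.right_end.describe()}) is "
                f"incompatible with {b.name!r} left end ({b.left_end.describe()})"
            )
    seq_parts = []
    feats: list[Feature] = []
    offset = 0
    for frag in fragments:
        seq_parts.append(frag.seq)
        for f in frag.features:
            segs = tuple((s + offset, e + offset) for s, e in f.location.segments)
            feats.append(replace(f, location=Location(segs, f.location.strand)))
        offset += len(frag.seq)
    seq = "".join(seq_parts)
    feats = _restore_features(feats, seq, topology)
    if topology == CIRCULAR:
        return DsDna(name=name, seq=seq, topology=CIRCULAR, features=feats)
    return DsDna(
        name=name,
        seq=seq,
        topology=LINEAR,
        left_end=fragments[0].left_end,
        right_end=fragments[-1].right_end,
        features=feats,
    )


# ---------------------------------------------------------------------------
# structural end modification

def _shift_features(feats, delta):
    out = []
    for f in feats:
        segs = tuple((s + delta, e + delta) for s, e in f.location.segments)
        out.append(replace(f, location=Location(segs, f.location.strand)))
    return out


def _mod_left(dna: DsDna, mod: EndModification) -> DsDna:
    """Apply an extend/trim at the LEFT end (the right-end case is reduced
    to this by flipping)."""
    L = len(dna.seq)
    left, right = dna.left_end, dna.right_end
    x, y = _duplex_bounds(dna)
    duplex = y - x
    if mod.mode == "extend":
        s = normalize_sequence(mod.seq)
        n = len(s)
        if mod.strand == "top":
            if left.kind == THREE_PRIME:
                o = left.overhang_seq
                k = len(o)
                m = min(n, k)
                if s[n - m :] != reverse_complement(o)[k - m : k - m + m]:
                    raise EndModificationError(
                        "top-strand extension does not complement the existing "
                        "3' overhang"
                    )
                if n < k:
                    new_left = EndStructure(THREE_PRIME, o[n:])
                elif n == k:
                    new_left = BLUNT_END
                else:
                    new_left = EndStructure(FIVE_PRIME, s[: n - k])
            else:
                o = left.overhang_seq if left.kind == FIVE_PRIME else ""
                new_left = EndStructure(FIVE_PRIME, s + o)
            return DsDna(
                name=dna.name, seq=s + dna.seq, topology=LINEAR, left_end=new_left,
                right_end=right, features=_shift_features(dna.features, n),
            )
        else:  # bottom, 3' end of the bottom strand is at the left
            if left.kind == FIVE_PRIME:
                o = left.overhang_seq
                k = len(o)
                m = min(n, k)
                if s[:m] != reverse_complement(o)[:m]:
                    raise EndModificationError(
                        "bottom-strand extension does not complement the existing "
                        "5' overhang"
                    )
                if n < k:
                    new_left = EndStructure(FIVE_PRIME, o[: k - n])
                elif n == k:
                    new_left = BLUNT_END
                else:
                    new_left = EndStructure(THREE_PRIME, s[k:])
            elif left.kind == THREE_PRIME:
                new_left = EndStructure(THREE_PRIME, left.overhang_seq + s)
            else:
                new_left = EndStructure(THREE_PRIME, s)
            return DsDna(
                name=dna.name, seq=dna.seq, topology=LINEAR, left_end=new_left,
                right_end=right, features=list(dna.features),
            )
    # trim
    n = mod.length
    if mod.strand == "top":
        k5 = left.length if left.kind == FIVE_PRIME else 0
        if n - k5 >= duplex:
            raise EndModificationError(
                f"trimming {n} nt from the top strand exceeds the double-stranded "
                f"span ({duplex} nt)"
            )
        if left.kind == FIVE_PRIME:
            o = left.overhang_seq
            if n < len(o):
                new_left = EndStructure(FIVE_PRIME, o[n:])
            elif n == len(o):
                new_left = BLUNT_END
            else:
                new_left = EndStructure(
                    THREE_PRIME, reverse_complement(dna.seq[len(o) : n])
                )
        elif left.kind == THREE_PRIME:
            new_left = EndStructure(
                THREE_PRIME, reverse_complement(dna.seq[:n]) + left.overhang_seq
            )
        else:
            new_left = EndStructure(THREE_PRIME, reverse_complement(dna.seq[:n]))
        feats = _extract_window(dna, n, L)
        return DsDna(name=dna.name, seq=dna.seq[n:], topology=LINEAR,
                     left_end=new_left, right_end=right, features=feats)
    else:  # bottom trim at left (3' end of bottom)
        k3 = left.length if left.kind == THREE_PRIME else 0
        if n - k3 >= duplex:
            raise EndModificationError(
                f"trimming {n} nt from the bottom strand exceeds the double-stranded "
                f"span ({duplex} nt)"
            )
        if left.kind == THREE_PRIME:
            o = left.overhang_seq
            if n < len(o):
                new_left = EndStructure(THREE_PRIME, o[: len(o) - n])
            elif n == len(o):
                new_left = BLUNT_END
            else:
                new_left = EndStructure(FIVE_PRIME, dna.seq[: n - len(o)])
        elif left.kind == FIVE_PRIME:
            o = left.overhang_seq
            new_left = EndStructure(FIVE_PRIME, dna.seq[: len(o) + n])
        else:
            new_left = EndStructure(FIVE_PRIME, dna.seq[:n])
        return DsDna(name=dna.name, seq=dna.seq, topology=LINEAR, left_end=new_left,
                     right_end=right, features=list(dna.features))


def _structural_modify(dna: DsDna, mods) -> DsDna:
    if dna.is_circular:
        raise EndModificationError("modify_ends requires a linear molecule")
    cur = dna
    for mod in mods:
        if mod.side == "left":
            cur = _mod_left(cur, mod)
        else:
            other = "bottom" if mod.strand == "top" else "top"
            mirrored = EndModification(
                "left", mod.mode, other, seq=mod.seq, length=mod.length
            )
            cur = _structural_flip(_mod_left(_structural_flip(cur), mirrored))
    feats = _restore_features(cur.features, cur.seq, LINEAR)
    return DsDna(name=dna.name, seq=cur.seq, topology=LINEAR, left_end=cur.left_end,
                 right_end=cur.right_end, features=feats)


# ---------------------------------------------------------------------------
# recorded public operations

def cut(dna: DsDna, *cuts: CutSpec) -> list[DsDna]:
    """Segment a molecule at one or more dual-strand cut positions.

    A circular molecule with n cuts yields n linear fragments; a linear one
    yields n+1, ordered 5'->3' by top-strand position.  Features spanning a
    cut are inherited piecewise with broken-piece qualifiers.
    """
    frags = _structural_cut(dna, list(cuts))
    provenance.record_operation(
        "cut",
        {"input": provenance.ref(dna), "cuts": [c.to_obj() for c in cuts]},
        inputs=[dna],
        outputs=frags,
    )
    return frags


@provenance.register_op("cut")
def _exec_cut(args, resolve):
    dna = resolve(args["input"])
    return cut(dna, *(CutSpec.from_obj(o) for o in args["cuts"]))


def crop(dna: DsDna, start_cut: CutSpec, end_cut: CutSpec) -> DsDna:
    """Extract the segment bound by two cut sites (a branch of cut).  On
    circular molecules the segment may wrap through the origin."""
    L = len(dna.seq)
    _prepare_cuts(dna, [start_cut, end_cut])  # validation only
    st, sb = start_cut.top_cut, start_cut.bottom_cut
    et, eb = end_cut.top_cut, end_cut.bottom_cut
    if dna.is_circular:
        st %= L
        sb = _near(sb % L, st, L)
        et %= L
        eb = _near(eb % L, et, L)
        if et <= st:
            et, eb = et + L, eb + L
    elif et < st:
        raise CutError("end cut lies before start cut on a linear molecule")
    frag = _fragment_between(dna, (st, sb), (et, eb), f"{dna.name}_crop")
    provenance.record_operation(
        "crop",
        {
            "input": provenance.ref(dna),
            "start_cut": start_cut.to_obj(),
            "end_cut": end_cut.to_obj(),
        },
        inputs=[dna],
        outputs=[frag],
    )
    return frag


@provenance.register_op("crop")
def _exec_crop(args, resolve):
    return [
        crop(
            resolve(args["input"]),
            CutSpec.from_obj(args["start_cut"]),
            CutSpec.from_obj(args["end_cut"]),
        )
    ]


def flip(dna: DsDna) -> DsDna:
    """Reverse-complement the molecule: feature strands toggle, coordinates
    remap, end structures swap sides with kind preserved."""
    out = _structural_flip(dna)
    provenance.record_operation(
        "flip", {"input": provenance.ref(dna)}, inputs=[dna], outputs=[out]
    )
    return out


@provenance.register_op("flip")
def _exec_flip(args, resolve):
    return [flip(resolve(args["input"]))]


def join(fragments, result_topology: str = LINEAR, name: str | None = None) -> DsDna:
    """Assemble fragments in the given order.  Every junction (and, for a
    circular result, the wrap-around junction) must be blunt/blunt or carry
    reverse-complementary overhangs of the same class.  Broken features whose
    pieces become adjacent with contiguous spans are restored."""
    fragments = list(fragments)
    if name is None:
        name = (fragments[0].name if fragments else "assembly") + "_join"
    out = _structural_join(fragments, result_topology, name)
    provenance.record_operation(
        "join",
        {
            "inputs": [provenance.ref(f) for f in fragments],
            "topology": result_topology,
            "name": name,
        },
        inputs=fragments,
        outputs=[out],
    )
    return out


@provenance.register_op("join")
def _exec_join(args, resolve):
    return [
        join([resolve(r) for r in args["inputs"]], args["topology"], args["name"])
    ]


def modify_ends(dna: DsDna, *mods: EndModification) -> DsDna:
    """Add or remove single-stranded sequence at the ends of a linear
    molecule.  Extending both strands with complementary texts lengthens the
    duplex; trimming one strand exposes (or lengthens) an overhang on the
    other."""
    out = _structural_modify(dna, list(mods))
    provenance.record_operation(
        "modify_ends",
        {"input": provenance.ref(dna), "mods": [m.to_obj() for m in mods]},
        inputs=[dna],
        outputs=[out],
    )
    return out


@provenance.register_op("modify_ends")
def _exec_modify_ends(args, resolve):
    return [
        modify_ends(
            resolve(args["input"]), *(EndModification.from_obj(o) for o in args["mods"])
        )
    ]
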