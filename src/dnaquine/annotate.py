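"""Search and direct-edit operations.

Two search functions (DNA sequence, annotation features) and two direct
edit functions (sequence, features).  Sequence search accepts IUPAC
degenerate queries (optionally with a Hamming mismatch budget) or regular
expressions; feature search matches the type key and qualifier values by
exact text, regular expression, or Levenshtein fuzzy matching.

Searches are recorded into the searched molecule's history (they are part
of the construction narrative: restriction sites and primer annealing
regions are *found*, not assumed), but return transient values — matches
are not persisted as features unless explicitly created via edit_feature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from . import provenance
from .errors import FeatureError, SearchError, SelectorError
from .model import (
    CIRCULAR,
    LINEAR,
    DsDna,
    Feature,
    Location,
    SeqMatch,
    feature_hash,
    normalize_sequence,
    reverse_complement,
)
from .topology import CutSpec, _extract_window, _renumber, _restore_features

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def _iupac_to_regex(pattern: str) -> str:
    out = []
    for i, ch in enumerate(pattern):
        exp = IUPAC.get(ch)
        if exp is None:
            raise SearchError(f"invalid IUPAC code {ch!r} at position {i}")
        out.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(out)


def _iupac_hit(text: str, pattern: str, max_mismatch: int) -> int | None:
    """Hamming mismatches of ``pattern`` against ``text`` (equal lengths),
    or None when over budget."""
    mism = 0
    for t, p in zip(text, pattern):
        if t not in IUPAC[p]:
            mism += 1
            if mism > max_mismatch:
                return None
    return mism


def _scan_plus(seq: str, circular: bool, pattern: str, is_regex: bool, max_mismatch: int):
    """All (start, length, mismatches) on the given top-strand text; start is
    always in [0, L) but start+length may wrap on circular molecules."""
    L = len(seq)
    hits = []
    if is_regex:
        text = seq + seq[:-1] if circular and L > 1 else seq
        try:
            rx = re.compile(f"(?=({pattern}))")
        except re.error as exc:
            raise SearchError(f"malformed regular expression: {exc}") from exc
        for m in rx.finditer(text):
            s, g = m.start(), m.group(1)
            if s < L and len(g) <= L:
                hits.append((s, len(g), 0))
    else:
        q = pattern
        n = len(q)
        if n == 0 or n > L:
            return []
        text = seq + seq[: n - 1] if circular else seq
        if max_mismatch == 0:
            rx = re.compile(f"(?=({_iupac_to_regex(q)}))")
            for m in rx.finditer(text):
                if m.start() < L:
                    hits.append((m.start(), n, 0))
        else:
            _iupac_to_regex(q)  # validate codes
            for s in range(min(L, len(text) - n + 1)):
                mm = _iupac_hit(text[s : s + n], q, max_mismatch)
                if mm is not None:
                    hits.append((s, n, mm))
    return hits


def search_sequence(
    dna: DsDna,
    query: str,
    strand: str = "both",
    max_mismatch: int = 0,
    is_regex: bool = False,
) -> list[SeqMatch]:
    """All occurrences of a query on the requested strands, including
    origin-spanning ones on circular molecules.  Minus-strand matches are
    reported in top-strand coordinates with strand '-'; every overlapping
    match is reported; ordering is (start, strand)."""
    if not query:
        raise SearchError("empty query")
    if is_regex and max_mismatch:
        raise SearchError("mismatch budget applies only to IUPAC queries")
    if strand not in ("+", "-", "both"):
        raise SearchError(f"bad strand {strand!r}")
    L = len(dna.seq)
    matches: list[SeqMatch] = []
    doubled = dna.seq + dna.seq
    if strand in ("+", "both"):
        for s, n, mm in _scan_plus(dna.seq, dna.is_circular, query.upper() if not is_regex else query, is_regex, max_mismatch):
            matches.append(SeqMatch(s, s + n, "+", doubled[s : s + n], mm))
    if strand in ("-", "both"):
        if is_regex:
            # scan the reverse-complement strand text, then map coordinates
            rc_seq = reverse_complement(dna.seq)
            for s, n, mm in _scan_plus(rc_seq, dna.is_circular, query, True, 0):
                start = (L - (s + n)) % L if dna.is_circular else L - (s + n)
                matches.append(
                    SeqMatch(start, start + n, "-", reverse_complement(doubled[start : start + n]), mm)
                )
        else:
            pat = iupac_reverse_complement(query.upper())
            for s, n, mm in _scan_plus(dna.seq, dna.is_circular, pat, False, max_mismatch):
                matches.append(
                    SeqMatch(s, s + n, "-", reverse_complement(doubled[s : s + n]), mm)
                )
    matches.sort(key=lambda m: (m.start, m.strand))
    provenance.record_operation(
        "search_sequence",
        {
            "input": provenance.ref(dna),
            "query": query,
            "strand": strand,
            "max_mismatch": max_mismatch,
            "is_regex": is_regex,
        },
        inputs=[dna],
        outputs=[],
        attach_to=dna,
    )
    return matches


@provenance.register_op("search_sequence")
def _exec_search_sequence(args, resolve):
    search_sequence(
        resolve(args["input"]),
        args["query"],
        args["strand"],
        args["max_mismatch"],
        args["is_regex"],
    )
    return []


@dataclass(frozen=True)
class RESpec:
    """A restriction enzyme rule: IUPAC recognition text plus top/bottom cut
    offsets relative to the recognition start (offsets beyond the recognition
    length describe Type IIS enzymes)."""

    name: str
    recognition: str
    top_offset: int
    bottom_offset: int

    def to_obj(self):
        return [self.name, self.recognition, self.top_offset, self.bottom_offset]

    @staticmethod
    def from_obj(obj) -> "RESpec":
        return RESpec(obj[0], obj[1], int(obj[2]), int(obj[3]))


def find_re_sites(dna: DsDna, enzyme: RESpec) -> list[CutSpec]:
    """One CutSpec per recognition site on either strand; minus-strand sites
    produce mirrored offsets; sites whose cut positions fall outside a linear
    molecule are discarded.  Palindromic sites found on both strands yield a
    single CutSpec."""
    L = len(dna.seq)
    cuts: list[CutSpec] = []
    seen: set[tuple[int, int]] = set()
    _iupac_to_regex(enzyme.recognition.upper())  # validate codes up front
    n = len(enzyme.recognition)
    for s, _n, _mm in _scan_plus(dna.seq, dna.is_circular, enzyme.recognition.upper(), False, 0):
        t, b = s + enzyme.top_offset, s + enzyme.bottom_offset
        _add_cut(cuts, seen, t, b, enzyme.name, L, dna.is_circular)
    pat = iupac_reverse_complement(enzyme.recognition.upper())
    for s, _n, _mm in _scan_plus(dna.seq, dna.is_circular, pat, False, 0):
        e = s + n
        t, b = e - enzyme.bottom_offset, e - enzyme.top_offset
        _add_cut(cuts, seen, t, b, enzyme.name, L, dna.is_circular)
    cuts.sort(key=lambda c: (c.top_cut, c.bottom_cut))
    provenance.record_operation(
        "find_re_sites",
        {"input": provenance.ref(dna), "enzyme": enzyme.to_obj()},
        inputs=[dna],
        outputs=[],
        attach_to=dna,
    )
    return cuts


def _add_cut(cuts, seen, t, b, label, L, circular):
    if circular:
        t %= L
        b %= L
    elif not (0 < t < L and 0 < b < L):
        return  # unusable site near a linear end
    key = (t, b)
    if key not in seen:
        seen.add(key)
        cuts.append(CutSpec(t, b, label))


@provenance.register_op("find_re_sites")
def _exec_find_re_sites(args, resolve):
    find_re_sites(resolve(args["input"]), RESpec.from_obj(args["enzyme"]))
    return []


# ---------------------------------------------------------------------------
# feature search

@dataclass(frozen=True)
class FeatureQuery:
    """Selector for features: key pattern and/or qualifier value pattern.

    mode: "text" (exact substring), "regex", or "fuzzy" (Levenshtein
    distance <= max_edits against the whole qualifier value).
    """

    key_pattern: str | None = None
    qualifier_label: str | None = None
    value_pattern: str | None = None
    mode: str = "text"
    max_edits: int = 0

    def __post_init__(self):
        if self.key_pattern is None and self.value_pattern is None:
            raise SearchError("a feature query needs a key pattern or a value pattern")
        if self.mode not in ("text", "regex", "fuzzy"):
            raise SearchError(f"bad match mode {self.mode!r}")
        if self.max_edits < 0:
            raise SearchError("max_edits must be >= 0")

    def to_obj(self):
        return {
            "key_pattern": self.key_pattern,
            "qualifier_label": self.qualifier_label,
            "value_pattern": self.value_pattern,
            "mode": self.mode,
            "max_edits": self.max_edits,
        }

    @staticmethod
    def from_obj(obj) -> "FeatureQuery":
        return FeatureQuery(
            obj.get("key_pattern"),
            obj.get("qualifier_label"),
            obj.get("value_pattern"),
            obj.get("mode", "text"),
            int(obj.get("max_edits", 0)),
        )


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Plain edit distance with an optional early-exit band limit."""
    if a == b:
        return 0
    if len(a) > len(b):
        a, b = b, a
    prev = list(range(len(a) + 1))
    for j, cb in enumerate(b, start=1):
        cur = [j]
        for i, ca in enumerate(a, start=1):
            cur.append(min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + (ca != cb)))
        prev = cur
        if limit is not None and min(prev) > limit:
            return limit + 1
    return prev[-1]


def _feature_matches(feat: Feature, q: FeatureQuery) -> bool:
    if q.key_pattern is not None:
        try:
            if re.fullmatch(q.key_pattern, feat.key) is None:
                return False
        except re.error as exc:
            raise SearchError(f"malformed key pattern: {exc}") from exc
    if q.value_pattern is None:
        return True
    values = [
        v for k, v in feat.qualifiers if q.qualifier_label in (None, k)
    ]
    if q.mode == "text":
        return any(q.value_pattern in v for v in values)
    if q.mode == "regex":
        try:
            rx = re.compile(q.value_pattern)
        except re.error as exc:
            raise SearchError(f"malformed value pattern: {exc}") from exc
        return any(rx.search(v) for v in values)
    return any(
        levenshtein(v, q.value_pattern, q.max_edits) <= q.max_edits for v in values
    )


def search_feature(dna: DsDna, query: FeatureQuery) -> list[Feature]:
    """Features whose key matches the key pattern and (if given) whose
    qualifier values match the value pattern under the chosen mode."""
    hits = [f for f in dna.sorted_features() if _feature_matches(f, query)]
    provenance.record_operation(
        "search_feature",
        {"input": provenance.ref(dna), "query": query.to_obj()},
        inputs=[dna],
        outputs=[],
        attach_to=dna,
    )
    return hits


@provenance.register_op("search_feature")
def _exec_search_feature(args, resolve):
    search_feature(resolve(args["input"]), FeatureQuery.from_obj(args["query"]))
    return []


# ---------------------------------------------------------------------------
# direct edits

def edit_sequence(dna: DsDna, target, replacement: str = "") -> DsDna:
    """Replace the target region (a SeqMatch or a (start, end) pair) with the
    given text (empty = deletion).  Equal-length substitutions leave every
    feature location untouched; insertions/deletions shift downstream
    features and break overlapping ones into pieces."""
    if isinstance(target, SeqMatch):
        s, e = target.start, target.end
    else:
        s, e = int(target[0]), int(target[1])
    L = len(dna.seq)
    if not (0 <= s <= e <= L):
        raise FeatureError(f"edit target [{s}, {e}) out of bounds for length {L}")
    rep = normalize_sequence(replacement) if replacement else ""
    new_seq = dna.seq[:s] + rep + dna.seq[e:]
    delta = len(rep) - (e - s)
    if delta == 0:
        feats = list(dna.features)
    else:
        left = _extract_window(dna, 0, s)
        right = _extract_window(dna, e, L)
        shifted = []
        for f in right:
            segs = tuple((a + s + len(rep), b + s + len(rep)) for a, b in f.location.segments)
            shifted.append(replace(f, location=Location(segs, f.location.strand)))
        feats = _renumber(left + shifted)
        feats = _restore_features(feats, new_seq, dna.topology)
    out = DsDna(
        name=dna.name,
        seq=new_seq,
        topology=dna.topology,
        left_end=dna.left_end,
        right_end=dna.right_end,
        features=feats,
    )
    provenance.record_operation(
        "edit_sequence",
        {"input": provenance.ref(dna), "start": s, "end": e, "replacement": rep},
        inputs=[dna],
        outputs=[out],
    )
    return out


@provenance.register_op("edit_sequence")
def _exec_edit_sequence(args, resolve):
    return [
        edit_sequence(
            resolve(args["input"]), (args["start"], args["end"]), args["replacement"]
        )
    ]


def edit_feature(dna: DsDna, action: str, payload) -> DsDna:
    """Create, remove, or update features.

    create: payload = Feature (or (key, location, qualifiers)); a fresh
    feature_id is assigned.  remove: payload = FeatureQuery.  update:
    payload = (FeatureQuery, changes dict with optional "key",
    "qualifier_updates" {label: value}, "qualifier_removals" [label]);
    feature_id is preserved.
    """
    if action == "create":
        if isinstance(payload, Feature):
            key, loc, quals = payload.key, payload.location, payload.qualifiers
        else:
            key, loc, quals = payload
            quals = tuple(tuple(q) for q in quals)
        _check_bounds(loc, len(dna.seq), dna.is_circular)
        fid = feature_hash(key, loc, quals, dna.record_id)
        new = Feature(key, loc, quals, fid)
        feats = dna.features + [new]
        args_payload = {"feature": new.to_obj()}
    elif action in ("remove", "update"):
        if action == "remove":
            query, changes = payload, None
        else:
            query, changes = payload
        matched = [f for f in dna.features if _feature_matches(f, query)]
        if not matched:
            raise SelectorError(f"feature selector matched nothing: {query}")
        if action == "remove":
            ids = {f.feature_id for f in matched}
            feats = [f for f in dna.features if f.feature_id not in ids]
            args_payload = {"query": query.to_obj()}
        else:
            feats = []
            for f in dna.features:
                if f in matched:
                    g = f
                    if changes.get("key"):
                        g = replace(g, key=changes["key"])
                    if changes.get("qualifier_removals"):
                        g = g.without_qualifiers(set(changes["qualifier_removals"]))
                    if changes.get("qualifier_updates"):
                        g = g.with_qualifiers(dict(changes["qualifier_updates"]))
                    feats.append(g)
                else:
                    feats.append(f)
            args_payload = {
                "query": query.to_obj(),
                "changes": {
                    "key": changes.get("key"),
                    "qualifier_updates": sorted(
                        (list(kv) for kv in dict(changes.get("qualifier_updates") or {}).items())
                    ),
                    "qualifier_removals": sorted(changes.get("qualifier_removals") or []),
                },
            }
    else:
        raise FeatureError(f"unknown edit_feature action {action!r}")
    out = DsDna(
        name=dna.name,
        seq=dna.seq,
        topology=dna.topology,
        left_end=dna.left_end,
        right_end=dna.right_end,
        features=feats,
    )
    provenance.record_operation(
        "edit_feature",
        {"input": provenance.ref(dna), "action": action, **args_payload},
        inputs=[dna],
        outputs=[out],
    )
    return out


def _check_bounds(loc: Location, L: int, circular: bool):
    if loc.crosses_origin and not circular:
        raise FeatureError("origin-spanning location on a linear molecule")
    for s, e in loc.segments:
        if not (0 <= s < e <= L):
            raise FeatureError(f"feature segment [{s}, {e}) out of bounds for length {L}")


@provenance.register_op("edit_feature")
def _exec_edit_feature(args, resolve):
    dna = resolve(args["input"])
    action = args["action"]
    if action == "create":
        f = Feature.from_obj(args["feature"])
        out = edit_feature(dna, "create", (f.key, f.location, f.qualifiers))
    elif action == "remove":
        out = edit_feature(dna, "remove", FeatureQuery.from_obj(args["query"]))
    else:
        ch = args["changes"]
        out = edit_feature(
            dna,
            "update",
            (
                FeatureQuery.from_obj(args["query"]),
                {
                    "key": ch.get("key"),
                    "qualifier_updates": dict(tuple(kv) for kv in ch.get("qualifier_updates") or []),
                    "qualifier_removals": list(ch.get("qualifier_removals") or []),
                },
            ),
        )
    return [out]
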