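"""Annotated double-stranded DNA model.

Conventions used throughout the package:

* Coordinates are 0-based, half-open, on the **top strand** (5'->3').
  GenBank serialization converts to 1-based inclusive.
* ``DsDna.seq`` holds the top strand only.  Single-stranded protrusions of
  the *bottom* strand at a linear end (a 5' overhang at the right end, a 3'
  overhang at the left end) are not part of ``seq``; they live in the end
  structures.  A consequence that the join/cut arithmetic relies on: at any
  ligatable junction exactly one of the two partners carries the annealed
  overhang on its top strand, so top strands simply concatenate.
* Overhang sequences are always written 5'->3' along the protruding strand,
  whichever strand that is.  Two sticky ends anneal iff they have the same
  kind (5' with 5', 3' with 3') and their overhang texts are exact reverse
  complements.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

from .errors import AlphabetError, TopologyError
from . import provenance

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LINEAR = "linear"
CIRCULAR = "circular"

BLUNT = "blunt"
FIVE_PRIME = "five_prime_overhang"
THREE_PRIME = "three_prime_overhang"


def normalize_sequence(seq: str) -> str:
    """Uppercase and validate a nucleotide string.

    Raises AlphabetError naming the first offending position.
    """
    if not seq:
        raise AlphabetError("empty sequence")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in ALPHABET:
            raise AlphabetError(f"invalid character {ch!r} at position {i}")
    return up


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    up = normalize_sequence(seq)
    return up.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EndStructure:
    """One end of a linear molecule.

    kind: blunt | five_prime_overhang | three_prime_overhang.
    overhang_seq: the protrusion read 5'->3' along the protruding strand;
    empty iff blunt.
    """

    kind: str = BLUNT
    overhang_seq: str = ""

    def __post_init__(self):
        if (self.kind == BLUNT) != (self.overhang_seq == ""):
            raise ValueError("overhang_seq must be empty iff blunt")
        if self.kind not in (BLUNT, FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown end kind {self.kind!r}")

    @property
    def length(self) -> int:
        return len(self.overhang_seq)

    def describe(self) -> str:
        if self.kind == BLUNT:
            return "blunt"
        tag = "5'" if self.kind == FIVE_PRIME else "3'"
        return f"{tag} overhang {self.overhang_seq}"


BLUNT_END = EndStructure()


@dataclass(frozen=True)
class Location:
    """A strand-aware, possibly origin-spanning, possibly multi-segment span.

    segments: ordered (start, end) half-open intervals in top coordinates.
    For a circular origin-spanning location the segments are stored wrapped
    ([m, L) then [0, n)) and crosses_origin is set.
    """

    segments: tuple[tuple[int, int], ...]
    strand: str = "+"
    crosses_origin: bool = False

    @staticmethod
    def single(start: int, end: int, strand: str = "+") -> "Location":
        return Location(((start, end),), strand)

    @staticmethod
    def from_linear(start: int, end: int, strand: str, length: int) -> "Location":
        """Build from a linearized interval where end may exceed ``length``
        (wrap through the origin of a circular molecule)."""
        span = end - start
        start %= length
        e = start + span
        if e <= length:
            return Location(((start, e),), strand)
        return Location(((start, length), (0, e - length)), strand, crosses_origin=True)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def linearized(self, mol_length: int) -> tuple[int, int]:
        """Return (start, end) with end possibly > mol_length for an
        origin-spanning location.  Only meaningful for contiguous locations
        (single segment, or the two wrapped halves)."""
        if not self.crosses_origin:
            return self.start, self.end
        (s, _e1), (_z, e2) = self.segments[0], self.segments[-1]
        return s, mol_length + e2

    def to_obj(self):
        return {
            "segments": [list(s) for s in self.segments],
            "strand": self.strand,
            "crosses_origin": self.crosses_origin,
        }

    @staticmethod
    def from_obj(obj) -> "Location":
        return Location(
            tuple((int(s), int(e)) for s, e in obj["segments"]),
            obj.get("strand", "+"),
            bool(obj.get("crosses_origin", False)),
        )


@dataclass(frozen=True)
class Feature:
    """An annotation: a type key, a location, ordered qualifiers and a stable
    identity token that survives inheritance and fragmentation."""

    key: str
    location: Location
    qualifiers: tuple[tuple[str, str], ...] = ()
    feature_id: str = ""

    def qualifier(self, label: str) -> str | None:
        for k, v in self.qualifiers:
            if k == label:
                return v
        return None

    def with_qualifiers(self, quals: dict[str, str]) -> "Feature":
        """Return a copy with the given labels replaced/appended."""
        out = [(k, v) for k, v in self.qualifiers if k not in quals]
        out.extend(quals.items())
        return replace(self, qualifiers=tuple(out))

    def without_qualifiers(self, labels) -> "Feature":
        return replace(
            self, qualifiers=tuple((k, v) for k, v in self.qualifiers if k not in labels)
        )

    def to_obj(self):
        return {
            "key": self.key,
            "location": self.location.to_obj(),
            "qualifiers": [list(q) for q in self.qualifiers],
            "feature_id": self.feature_id,
        }

    @staticmethod
    def from_obj(obj) -> "Feature":
        return Feature(
            obj["key"],
            Location.from_obj(obj["location"]),
            tuple((k, v) for k, v in obj.get("qualifiers", [])),
            obj.get("feature_id", ""),
        )


@dataclass(frozen=True)
class SeqMatch:
    """One sequence-search hit, in top-strand coordinates.

    For minus-strand matches ``matched_text`` is the query-strand text, i.e.
    the reverse complement of the top-strand span; ``end`` may exceed the
    molecule length for origin-spanning matches on circular molecules.
    """

    start: int
    end: int
    strand: str
    matched_text: str
    mismatches: int = 0


def feature_hash(key: str, location: Location, qualifiers, parent_token: str) -> str:
    payload = json.dumps(
        [key, location.to_obj(), [list(q) for q in qualifiers], parent_token],
        sort_keys=True,
        separators=(",", ":"),
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:8]


@dataclass
class DsDna:
    """An annotated double-stranded DNA molecule."""

    name: str
    seq: str
    topology: str = LINEAR
    left_end: EndStructure | None = None
    right_end: EndStructure | None = None
    features: list[Feature] = field(default_factory=list)
    history: list = field(default_factory=list)  # list[OperationRecord]
    _origin: tuple[str, int] | None = None  # (step_id, output index)

    def __post_init__(self):
        if self.topology == CIRCULAR:
            self.left_end = None
            self.right_end = None
        else:
            if self.left_end is None:
                self.left_end = BLUNT_END
            if self.right_end is None:
                self.right_end = BLUNT_END

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    @property
    def record_id(self) -> str:
        """Content-derived identity: a deterministic function of sequence,
        topology, end structures and canonicalized (order-independent)
        features.  Not invariant under rotation of a circular sequence."""
        ends = (
            []
            if self.is_circular
            else [
                [self.left_end.kind, self.left_end.overhang_seq],
                [self.right_end.kind, self.right_end.overhang_seq],
            ]
        )
        feats = sorted(
            (f.to_obj() for f in self.features),
            key=lambda o: json.dumps(o, sort_keys=True),
        )
        payload = json.dumps(
            [self.seq, self.topology, ends, feats], sort_keys=True, separators=(",", ":")
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def feature_by_id(self, feature_id: str) -> Feature | None:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        return None

    def sorted_features(self) -> list[Feature]:
        return sorted(
            self.features, key=lambda f: (f.location.start, f.key, f.feature_id)
        )


def subsequence(dna: DsDna, start: int, end: int) -> str:
    """Top-strand text of [start, end).  On circular molecules start > end
    (or end > length) wraps through the origin; on linear molecules that is
    a topology error."""
    L = len(dna.seq)
    if dna.is_circular:
        span = end - start if end >= start else end - start + L
        if not 0 <= span <= L:
            raise _range_error(start, end, L)
        s = start % L
        doubled = dna.seq + dna.seq
        return doubled[s : s + span]
    if not 0 <= start <= L or not 0 <= end <= L:
        raise _range_error(start, end, L)
    if end < start:
        raise TopologyError(
            f"subsequence [{start}, {end}) wraps through the origin of a linear molecule"
        )
    return dna.seq[start:end]


def _range_error(start, end, L):
    return TopologyError(f"positions [{start}, {end}) out of range for length {L}")


def feature_own_sequence(dna: DsDna, feat: Feature) -> str:
    """The nucleotide sequence of a feature read 5'->3' along its own strand."""
    text = "".join(subsequence(dna, s, e) for s, e in feat.location.segments)
    if feat.location.strand == "-":
        return reverse_complement(text)
    return text


def _features_to_obj(features) -> list:
    return [f.to_obj() for f in features]


def _build_source(name, seq, topology, feat_objs) -> DsDna:
    feats = [Feature.from_obj(o) for o in feat_objs]
    parent_token = hashlib.sha256(f"{seq}|{topology}".encode()).hexdigest()[:16]
    fixed = []
    for i, f in enumerate(feats):
        fid = f.feature_id or feature_hash(f.key, f.location, f.qualifiers, f"{parent_token}:{i}")
        fixed.append(replace(f, feature_id=fid))
    return DsDna(name=name, seq=seq, topology=topology, features=fixed)


def from_sequence(
    seq: str,
    topology: str = LINEAR,
    name: str = "dna",
    features: list[Feature] | None = None,
) -> DsDna:
    """Create a molecule from a raw sequence.

    The sequence (and any features) are embedded verbatim in the resulting
    source record, so scripts regenerated from descendants of this molecule
    are self-contained.
    """
    up = normalize_sequence(seq)
    if topology not in (LINEAR, CIRCULAR):
        raise TopologyError(f"unknown topology {topology!r}")
    feat_objs = _features_to_obj(features or [])
    return _recorded_source(name, up, topology, feat_objs)


def _recorded_source(name, seq, topology, feat_objs) -> DsDna:
    dna = _build_source(name, seq, topology, feat_objs)
    provenance.record_operation(
        "source",
        {"name": name, "seq": seq, "topology": topology,
         "features": _features_to_obj(dna.features)},
        inputs=[],
        outputs=[dna],
    )
    return dna


@provenance.register_op("source")
def _exec_source(args, resolve):
    return [_recorded_source(args["name"], args["seq"], args["topology"], args["features"])]
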