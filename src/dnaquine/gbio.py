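"""GenBank / FASTA input-output and text rendering.

A written GenBank file is a perfectly ordinary flat file — third-party
parsers see the history as plain qualifiers on a full-span ``source``
feature — yet it carries the complete construction history, one
percent-encoded ``building_history_<k>`` qualifier per operation record.
Reading such a file rehydrates and validates the records (every step id is
recomputed from its content), so the file can regenerate the script that
built it.

Encoding detail: Biopython wraps long qualifier values across lines and
rejoins them with spaces.  History payloads are percent-encoded with a safe
set that excludes the space character, and all spaces are stripped from the
values on read, which makes the embedding lossless.
"""

from __future__ import annotations

import json
import urllib.parse
import warnings

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import CorruptHistoryError, DnaQuineError
from .model import (
    BLUNT,
    CIRCULAR,
    LINEAR,
    DsDna,
    EndStructure,
    Feature,
    Location,
    complement,
    feature_hash,
    from_sequence,
)
from .provenance import (
    OperationRecord,
    compute_step_id,
    validate_history,
)

DIALECT_TAG = "qrs-v1"
_SAFE = "-._~"  # RFC 3986 unreserved (alphanumerics are implicitly safe)
_WRITE_DATE = "01-JAN-1980"  # fixed stamp: output is a pure function of content


def _encode_payload(obj) -> str:
    return urllib.parse.quote(
        json.dumps(obj, separators=(",", ":"), ensure_ascii=True), safe=_SAFE
    )


def _decode_payload(text: str):
    return json.loads(urllib.parse.unquote(text.replace(" ", "")))


def _locus_name(name: str) -> str:
    clean = "".join(c if c.isalnum() or c in "-_." else "_" for c in name)
    return (clean or "dna")[:16]


def _to_biopython_location(loc: Location):
    strand = -1 if loc.strand == "-" else 1
    parts = [SimpleLocation(s, e, strand) for s, e in loc.segments]
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def _from_biopython_location(bioloc, length: int, circular: bool) -> Location:
    strand = "-" if bioloc.strand == -1 else "+"
    parts = sorted(
        ((int(p.start), int(p.end)) for p in bioloc.parts), key=lambda t: t[0]
    )
    if (
        circular
        and len(parts) == 2
        and parts[1][1] == length
        and parts[0][0] == 0
    ):
        # join(m..L,1..n): wrapped through the origin
        return Location((parts[1], parts[0]), strand, crosses_origin=True)
    return Location(tuple(parts), strand)


def write_genbank(dna: DsDna, path) -> None:
    """Write a standard GenBank flat file with the construction history
    serialized as numbered qualifiers on a full-span source feature.
    Output is deterministic: byte-identical for equal molecules."""
    rec = SeqRecord(
        Seq(dna.seq),
        id=_locus_name(dna.name),
        name=_locus_name(dna.name),
        description=dna.name,
        annotations={
            "molecule_type": "DNA",
            "topology": dna.topology,
            "data_file_division": "SYN",
            "date": _WRITE_DATE,
        },
    )
    src_quals: dict[str, object] = {
        "label": [dna.name],
        "construction_dialect": [DIALECT_TAG],
    }
    if not dna.is_circular:
        src_quals["left_end"] = [f"{dna.left_end.kind}:{dna.left_end.overhang_seq}"]
        src_quals["right_end"] = [f"{dna.right_end.kind}:{dna.right_end.overhang_seq}"]
    if dna._origin is not None:
        src_quals["origin_ref"] = [f"{dna._origin[0]}#{dna._origin[1]}"]
    for k, r in enumerate(dna.history, start=1):
        payload = [
            r.step_id,
            r.op_name,
            r.canonical_args,
            list(r.parents),
            r.n_outputs,
            list(r.product_ref),
            r.process_name,
            r.process_description,
        ]
        src_quals[f"building_history_{k}"] = [_encode_payload(payload)]
    features = [SeqFeature(SimpleLocation(0, len(dna.seq), 1), type="source",
                           qualifiers=src_quals)]
    for f in dna.sorted_features():
        quals: dict[str, list[str]] = {}
        for k, v in f.qualifiers:
            quals.setdefault(k, []).append(v)
        quals["feature_id"] = [f.feature_id]
        features.append(
            SeqFeature(_to_biopython_location(f.location), type=f.key, qualifiers=quals)
        )
    rec.features = features
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "genbank")


def _rehydrate_history(src_quals) -> tuple[list[OperationRecord], tuple[str, int] | None]:
    items = []
    for key, values in src_quals.items():
        if key.startswith("building_history_"):
            items.append((int(key.rsplit("_", 1)[1]), values[0]))
    items.sort()
    history = []
    for _k, token in items:
        try:
            step_id, op, args, parents, n_out, prod, pname, pdesc = _decode_payload(token)
        except (ValueError, json.JSONDecodeError) as exc:
            raise CorruptHistoryError(f"undecodable history qualifier: {exc}") from exc
        if compute_step_id(op, args, parents) != step_id:
            raise CorruptHistoryError(
                f"step id {step_id} does not match its recorded content "
                f"(operation {op})"
            )
        history.append(
            OperationRecord(
                step_id=step_id,
                op_name=op,
                canonical_args=args,
                parents=tuple(parents),
                n_outputs=int(n_out),
                product_ref=tuple(prod),
                process_name=pname,
                process_description=pdesc,
            )
        )
    try:
        validate_history(history)
    except DnaQuineError as exc:
        raise CorruptHistoryError(str(exc)) from exc
    origin = None
    if "origin_ref" in src_quals:
        step, idx = src_quals["origin_ref"][0].replace(" ", "").split("#")
        origin = (step, int(idx))
    return history, origin


def _parse_end(text: str) -> EndStructure:
    kind, _, ovh = text.replace(" ", "").partition(":")
    if kind == BLUNT or not kind:
        return EndStructure()
    return EndStructure(kind, ovh)


def read_genbank(path) -> DsDna:
    """Read a GenBank file.  Files written by this package rehydrate their
    full history (validated step by step); plain files from elsewhere load
    as molecules whose single source record embeds the file content."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise DnaQuineError(f"no GenBank record in {path}")
    if len(records) > 1:
        warnings.warn(f"{path}: {len(records)} records; using the first only")
    rec = records[0]
    topology = CIRCULAR if rec.annotations.get("topology") == "circular" else LINEAR
    length = len(rec.seq)
    feats: list[Feature] = []
    src_quals = None
    for bf in rec.features:
        if bf.type == "source" and "construction_dialect" in bf.qualifiers:
            src_quals = bf.qualifiers
            continue
        quals = []
        fid = ""
        for k, values in bf.qualifiers.items():
            for v in values:
                if k == "feature_id":
                    fid = v
                else:
                    quals.append((k, v))
        loc = _from_biopython_location(bf.location, length, topology == CIRCULAR)
        if not fid:
            fid = feature_hash(bf.type, loc, quals, rec.id)
        feats.append(Feature(bf.type, loc, tuple(quals), fid))

    if src_quals is None:
        return from_sequence(str(rec.seq), topology, name=rec.name or rec.id,
                             features=feats)

    name = src_quals.get("label", [rec.name or rec.id])[0]
    history, origin = _rehydrate_history(src_quals)
    left = _parse_end(src_quals.get("left_end", ["blunt:"])[0]) if topology == LINEAR else None
    right = _parse_end(src_quals.get("right_end", ["blunt:"])[0]) if topology == LINEAR else None
    dna = DsDna(
        name=name,
        seq=str(rec.seq).upper(),
        topology=topology,
        left_end=left,
        right_end=right,
        features=feats,
        history=history,
    )
    dna._origin = origin
    return dna


def read_fasta(path) -> DsDna:
    """First FASTA record as a linear molecule (source record embeds it)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DnaQuineError(f"no FASTA record in {path}")
    if len(records) > 1:
        warnings.warn(f"{path}: {len(records)} records; using the first only")
    rec = records[0]
    return from_sequence(str(rec.seq), LINEAR, name=rec.id)


def write_fasta(dna: DsDna, path) -> None:
    if dna.features:
        warnings.warn(
            f"writing {dna.name!r} as FASTA drops {len(dna.features)} feature(s) "
            "and the construction history"
        )
    rec = SeqRecord(Seq(dna.seq), id=_locus_name(dna.name), description=dna.name)
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "fasta")


# ---------------------------------------------------------------------------
# text rendering

def print_sequence(dna: DsDna) -> str:
    """Both strands as two aligned text lines; single-stranded end regions
    show as spaces on the missing strand."""
    L = len(dna.seq)
    if dna.is_circular:
        return dna.seq + "\n" + complement(dna.seq)
    lo = {"five_prime_overhang": dna.left_end.length,
          "three_prime_overhang": -dna.left_end.length}.get(dna.left_end.kind, 0)
    hi = L + {"five_prime_overhang": dna.right_end.length,
              "three_prime_overhang": -dna.right_end.length}.get(dna.right_end.kind, 0)
    g0, g1 = min(lo, 0), max(hi, L)
    top = " " * (0 - g0) + dna.seq + " " * (g1 - L)
    bottom_chars = []
    for p in range(g0, g1):
        if not (lo <= p < hi):
            bottom_chars.append(" ")
        elif 0 <= p < L:
            bottom_chars.append(complement(dna.seq[p]))
        elif p < 0:
            bottom_chars.append(dna.left_end.overhang_seq[-1 - p])
        else:
            bottom_chars.append(dna.right_end.overhang_seq[hi - 1 - p])
    return top + "\n" + "".join(bottom_chars)


def location_str(loc: Location, length: int) -> str:
    """GenBank-style 1-based inclusive location text."""
    parts = [f"{s + 1}..{e}" for s, e in loc.segments]
    body = parts[0] if len(parts) == 1 else "join(" + ",".join(parts) + ")"
    return f"complement({body})" if loc.strand == "-" else body


def print_feature(dna: DsDna) -> str:
    """Feature table: one row per feature (id, key, location, strand,
    qualifiers)."""
    rows = [("feature_id", "key", "location", "strand", "qualifiers")]
    for f in dna.sorted_features():
        quals = "; ".join(f"{k}={v}" for k, v in f.qualifiers)
        rows.append(
            (f.feature_id, f.key, location_str(f.location, len(dna.seq)),
             f.location.strand, quals)
        )
    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    lines = []
    for r in rows:
        lines.append(
            "  ".join(str(r[i]).ljust(widths[i]) for i in range(4)) + "  " + r[4]
        )
    return "\n".join(lines)
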