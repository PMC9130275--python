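"""Content-addressed construction histories, quine scripts and replay.

Every public operation that creates or mutates molecules is recorded as an
OperationRecord.  A record's ``step_id`` is a truncated SHA-256 of the
operation name, its canonical JSON arguments and its sorted parent step ids,
so identical operations on identical inputs always produce identical ids —
across processes, serialization round trips and replays.

A molecule's ``history`` is the topologically ordered, de-duplicated union
of its parents' histories plus its own producing record.  From any complete
history a recipe script (the "quine") can be regenerated; replaying the
script through the same public operations rebuilds molecules whose record
ids, features and step ids equal the originals.

Script dialect (``.qrs``, version 1), one command per line::

    #qrs v1
    va1b2c3d4e5o0 = source {"features": [...], "name": ..., "seq": ..., ...}
    vf6e5d4c3b2o0 vf6e5d4c3b2o1 = cut {"cuts": [[3, 7, "EcoRI"]], "input": "@a1b2c3d4e5f60708#0"}
    ! search_sequence {"input": "@...#0", "query": "GAATTC", ...}

Output names are deterministic functions of the step id; ``!`` marks a
command with no molecule outputs (searches).  Molecule-valued arguments are
references ``@<step_id>#<output index>``.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field

from .errors import IncompleteHistoryError, ScriptError

DIALECT = "qrs v1"

SOURCE_OPS = ("source",)

# ---------------------------------------------------------------------------
# records

_process_stack: list[tuple[str, str]] = []


@contextmanager
def set_process(name: str, description: str = ""):
    """Group subsequent operations under a named procedure with a narrative
    description (used by methods-text export).  Nested contexts: innermost
    wins."""
    _process_stack.append((name, description))
    try:
        yield
    finally:
        _process_stack.pop()


def current_process() -> tuple[str, str] | None:
    return _process_stack[-1] if _process_stack else None


@dataclass(frozen=True)
class OperationRecord:
    step_id: str
    op_name: str
    canonical_args: str  # canonical JSON text
    parents: tuple[str, ...]
    n_outputs: int
    product_ref: tuple[str, ...] = ()  # record_ids of outputs
    process_name: str = ""
    process_description: str = ""

    @property
    def is_source(self) -> bool:
        return self.op_name in SOURCE_OPS

    def args(self) -> dict:
        return json.loads(self.canonical_args)


def canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(", ", ": "), ensure_ascii=True)


def compute_step_id(op_name: str, canonical_args: str, parents) -> str:
    payload = "|".join(["qrs1", op_name, canonical_args, ",".join(sorted(parents))])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def ref(dna) -> str:
    """Script reference for a molecule: @<producing step id>#<output index>."""
    if dna._origin is None:
        raise IncompleteHistoryError(
            f"molecule {dna.name!r} has no producing record (was it built outside "
            "the recorded operations?)"
        )
    step, idx = dna._origin
    return f"@{step}#{idx}"


def merge_histories(histories) -> list[OperationRecord]:
    """Topologically ordered, de-duplicated union.  Input histories are
    already topologically ordered, so an order-preserving merge suffices."""
    seen: set[str] = set()
    merged: list[OperationRecord] = []
    for hist in histories:
        for rec in hist:
            if rec.step_id not in seen:
                seen.add(rec.step_id)
                merged.append(rec)
    return merged


def record_operation(op_name, args: dict, inputs, outputs, process=None,
                     attach_to=None) -> OperationRecord:
    """Create the record for one operation invocation and wire the outputs.

    ``args`` must already contain molecule references (strings from ``ref``)
    in place of DsDna values.  ``inputs`` are the consumed molecules (their
    histories are inherited); ``outputs`` the produced ones.  For searches
    (no outputs) pass the searched molecule via ``attach_to``: the record is
    appended to that molecule's history in place.
    """
    proc = process if process is not None else current_process()
    if proc is not None:
        args = dict(args)
        args["_process"] = [proc[0], proc[1]]
    args_text = canonical_json(args)
    parents = tuple(dna._origin[0] for dna in inputs if dna._origin is not None)
    step_id = compute_step_id(op_name, args_text, parents)
    rec = OperationRecord(
        step_id=step_id,
        op_name=op_name,
        canonical_args=args_text,
        parents=parents,
        n_outputs=len(outputs),
        product_ref=tuple(d.record_id for d in outputs),
        process_name=proc[0] if proc else "",
        process_description=proc[1] if proc else "",
    )
    base = merge_histories([d.history for d in inputs])
    if any(r.step_id == step_id for r in base):
        # identical re-invocation (content addressing): keep the existing record
        hist = base
    else:
        hist = base + [rec]
    for k, dna in enumerate(outputs):
        dna.history = list(hist)
        dna._origin = (step_id, k)
    if attach_to is not None and not outputs:
        if not any(r.step_id == step_id for r in attach_to.history):
            attach_to.history = attach_to.history + [rec]
    return rec


# ---------------------------------------------------------------------------
# operation registry (filled by the op modules at import time)

_OP_REGISTRY: dict = {}


def register_op(name: str):
    def deco(func):
        _OP_REGISTRY[name] = func
        return func

    return deco


# ---------------------------------------------------------------------------
# quine generation

def _out_name(step_id: str, k: int) -> str:
    return f"v{step_id[:10]}o{k}"


def validate_history(history) -> None:
    """Closure under parents + topological order (parents precede children)."""
    seen = set()
    for rec in history:
        for p in rec.parents:
            if p not in seen:
                raise IncompleteHistoryError(
                    f"record {rec.step_id} ({rec.op_name}) references parent {p} "
                    "that is absent or out of order"
                )
        seen.add(rec.step_id)


@dataclass
class RecipeScript:
    """An ordered list of canonical commands; the unit emitted by quine
    generation and consumed by replay."""

    commands: list[tuple[list[str], str, str]] = field(default_factory=list)
    # each command: (output names, op name, canonical args JSON)

    def to_text(self) -> str:
        lines = [f"#{DIALECT}"]
        for names, op, args in self.commands:
            head = " ".join(names) + " = " if names else "! "
            lines.append(f"{head}{op} {args}")
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_text(text: str) -> "RecipeScript":
        lines = text.splitlines()
        if not lines or lines[0].strip() != f"#{DIALECT}":
            raise ScriptError(f"missing dialect header '#{DIALECT}'")
        script = RecipeScript()
        for ln, raw in enumerate(lines[1:], start=2):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("! "):
                names, rest = [], line[2:]
            else:
                if " = " not in line:
                    raise ScriptError(f"line {ln}: expected 'names = op {{...}}'")
                head, rest = line.split(" = ", 1)
                names = head.split()
            try:
                op, args = rest.split(" ", 1)
            except ValueError as exc:
                raise ScriptError(f"line {ln}: missing arguments") from exc
            try:
                json.loads(args)
            except json.JSONDecodeError as exc:
                raise ScriptError(f"line {ln}: bad argument JSON: {exc}") from exc
            script.commands.append((names, op, args))
        return script


def generate_quine(dna_or_path) -> RecipeScript:
    """Regenerate the recipe script that builds the given molecule (or
    GenBank file).  The script is a deterministic function of the history:
    regenerating it from a replayed product is byte-identical."""
    from . import gbio  # local import; gbio imports this module

    if isinstance(dna_or_path, (str,)) or hasattr(dna_or_path, "read_text"):
        dna = gbio.read_genbank(str(dna_or_path))
    else:
        dna = dna_or_path
    if not dna.history:
        raise IncompleteHistoryError(
            f"molecule {dna.name!r} carries no construction history"
        )
    validate_history(dna.history)
    script = RecipeScript()
    for rec in dna.history:
        names = [_out_name(rec.step_id, k) for k in range(rec.n_outputs)]
        script.commands.append((names, rec.op_name, rec.canonical_args))
    return script


# ---------------------------------------------------------------------------
# replay

def replay(script: RecipeScript) -> dict:
    """Execute a recipe script through the public operations, rebuilding
    histories identically.  Returns {assigned name -> DsDna}."""
    env: dict[str, object] = {}
    by_ref: dict[str, object] = {}

    def resolve(token: str):
        if not (isinstance(token, str) and token.startswith("@")):
            raise ScriptError(f"not a molecule reference: {token!r}")
        if token[1:].count("#") != 1:
            raise ScriptError(f"malformed reference {token!r}")
        if token not in by_ref:
            raise ScriptError(f"reference {token!r} is not defined earlier in the script")
        return by_ref[token]

    for idx, (names, op, args_text) in enumerate(script.commands):
        exec_fn = _OP_REGISTRY.get(op)
        if exec_fn is None:
            raise ScriptError(f"command {idx}: unknown operation {op!r}")
        args = json.loads(args_text)
        proc = args.pop("_process", None)
        try:
            if proc is not None:
                with set_process(proc[0], proc[1]):
                    outputs = exec_fn(args, resolve)
            else:
                outputs = exec_fn(args, resolve)
        except ScriptError:
            raise
        except Exception as exc:
            raise ScriptError(f"command {idx} ({op}): {exc}") from exc
        outputs = outputs or []
        if len(outputs) != len(names):
            raise ScriptError(
                f"command {idx} ({op}): produced {len(outputs)} outputs, "
                f"script names {len(names)}"
            )
        for k, (name, dna) in enumerate(zip(names, outputs)):
            step, _ = dna._origin
            expected = _out_name(step, k)
            if name != expected:
                raise ScriptError(
                    f"command {idx} ({op}): replay produced step {step}, which does "
                    f"not match the scripted name {name} — the script was edited "
                    "inconsistently or the history is corrupt"
                )
            env[name] = dna
            by_ref[f"@{step}#{k}"] = dna
    return env


# ---------------------------------------------------------------------------
# exports

def export_methods_text(dna) -> str:
    """Concatenate process descriptions in topological order, one paragraph
    per distinct process name; records without a description are skipped."""
    paragraphs: list[tuple[str, str]] = []
    seen_pairs = set()
    for rec in dna.history:
        if not rec.process_description:
            continue
        pair = (rec.process_name, rec.process_description)
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        if paragraphs and paragraphs[-1][0] == rec.process_name:
            paragraphs[-1] = (rec.process_name, paragraphs[-1][1] + " " + rec.process_description)
        else:
            paragraphs.append(pair)
    out = []
    for name, desc in paragraphs:
        out.append(f"{name}: {desc}" if name else desc)
    return "\n\n".join(out)


def export_flow_dot(dna) -> str:
    """Operational-history flow chart as DOT text.

    Node shapes: note = source inputs, box = operations, ellipse = molecule
    products.  Deterministic for a given history.
    """
    lines = ["digraph construction_flow {", "  rankdir=TB;"]
    for rec in dna.history:
        shape = "note" if rec.is_source else "box"
        label = rec.op_name if not rec.is_source else f"{rec.args().get('name', 'source')}"
        lines.append(f'  "op_{rec.step_id}" [shape={shape}, label="{label}"];')
        for k in range(rec.n_outputs):
            lines.append(
                f'  "mol_{rec.step_id}_{k}" [shape=ellipse, label="{_out_name(rec.step_id, k)}"];'
            )
            lines.append(f'  "op_{rec.step_id}" -> "mol_{rec.step_id}_{k}";')
    produced = {r.step_id: r.n_outputs for r in dna.history}
    for rec in dna.history:
        args = rec.args()
        for token in _iter_refs(args):
            step, k = token[1:].split("#")
            if step in produced:
                lines.append(f'  "mol_{step}_{k}" -> "op_{rec.step_id}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _iter_refs(obj):
    if isinstance(obj, str):
        if obj.startswith("@") and "#" in obj:
            yield obj
    elif isinstance(obj, dict):
        for v in obj.values():
            yield from _iter_refs(v)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _iter_refs(v)
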