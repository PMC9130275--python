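"""Exception hierarchy.

Every error raised on a user-facing path derives from DnaQuineError so that
callers (and the CLI) can catch one type.
"""


class DnaQuineError(Exception):
    """Base class for all package errors."""


class AlphabetError(DnaQuineError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class TopologyError(DnaQuineError):
    """An operation is not defined for the molecule's topology."""


class CutError(DnaQuineError):
    """Invalid cut specification (out of range, overlapping overhangs...)."""


class IncompatibleEndsError(DnaQuineError):
    """Two DNA ends cannot be joined (kind or overhang mismatch)."""


class EndModificationError(DnaQuineError):
    """Invalid end modification (circular input, trim past duplex...)."""


class SearchError(DnaQuineError):
    """Malformed search query (bad IUPAC code, bad regular expression)."""


class SelectorError(DnaQuineError):
    """A feature selector matched zero features for update/remove."""


class FeatureError(DnaQuineError):
    """Invalid feature payload (out-of-bounds location...)."""


class IncompleteHistoryError(DnaQuineError):
    """Quine generation requested on a molecule without a complete history."""


class CorruptHistoryError(DnaQuineError):
    """Embedded history failed step-id validation on rehydration."""


class ScriptError(DnaQuineError):
    """A recipe script is malformed or references an undefined name."""


class PrimerError(DnaQuineError):
    """A primer does not anneal, anneals ambiguously, or points the wrong way."""


class AssemblyError(DnaQuineError):
    """An assembly recipe cannot proceed (no site, no overlap, ambiguity)."""


class CircuitError(DnaQuineError):
    """A genetic-circuit query is ill-posed (e.g. promoter count != 1)."""
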