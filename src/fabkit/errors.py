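"""Exception hierarchy shared across fabkit modules."""


class FabkitError(Exception):
    """Base class for all fabkit errors."""


class ParseError(FabkitError):
    """Malformed input file (FASTA, CSV, TSV, structure, score table)."""


class ValidationError(FabkitError):
    """Input parsed but violates a domain invariant."""


class ArgumentError(FabkitError):
    """Caller violated an operation precondition."""


class DataInconsistencyError(FabkitError):
    """Mutually inconsistent inputs, e.g. ATOM sequence not contained in SEQRES."""


class GeometryError(FabkitError):
    """Degenerate or insufficient geometry for a structural computation."""


class InsufficientCorrespondenceError(GeometryError):
    """Fewer shared labelled positions than a superposition requires."""


class BatchLimitError(FabkitError):
    """Repertoire upload exceeds the configured batch maximum."""


class ScaleError(FabkitError):
    """Score-matrix scaling misuse (missing WT score, double scaling...)."""
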