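"""Exception hierarchy for the package."""


class VhhError(Exception):
    """Base class for all package errors."""


class ParseError(VhhError):
    """Malformed input file (FASTA/AIRR/PDB)."""


class ValidationError(VhhError):
    """A record violates an invariant (alphabet, frame, counts ...)."""


class SchemaError(VhhError):
    """A tabular input is missing mandatory columns."""


class ConsistencyError(VhhError):
    """Fields of one record contradict each other (e.g. region strings vs sequence)."""


class AnnotationError(VhhError):
    """Region annotation failed; carries the anchor that could not be located."""

    def __init__(self, message: str, anchor: str | None = None):
        super().__init__(message)
        self.anchor = anchor


class ConfigurationError(VhhError):
    """Invalid or empty user configuration (germline db, hinge motifs ...)."""


class GenerationError(VhhError):
    """Synthetic-data request is unsatisfiable (e.g. conflicting geometry)."""
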