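"""Exception hierarchy for resource loading, parsing and querying."""


class BioProcKGError(Exception):
    """Base class for all package errors."""


class InvalidDocumentError(BioProcKGError):
    """Raised for empty or structurally invalid input documents."""


class DocumentParseError(BioProcKGError):
    """Raised when XML input cannot be parsed; carries the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class ConfigurationError(BioProcKGError):
    """Missing identifiers, malformed run configuration, unknown keys."""


class IntegrityError(BioProcKGError):
    """Dangling cross-references between resources (ids listed in message)."""


class FormatError(BioProcKGError):
    """Malformed field values in resource tables (e.g. bad COID)."""


class AmbiguityError(BioProcKGError):
    """The same surface form maps to more than one dictionary concept."""


class CycleError(BioProcKGError):
    """A cycle over is_a edges in the class hierarchy."""

    def __init__(self, message: str, cycle=None):
        super().__init__(message)
        self.cycle = list(cycle or [])


class OntologyLookupError(BioProcKGError):
    """Reference to a class id or name that is not in the ontology."""


class QueryPatternError(BioProcKGError):
    """Malformed wildcard pattern in a graph query."""
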