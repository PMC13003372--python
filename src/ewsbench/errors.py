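"""Exception hierarchy shared across the package."""


class EwsbenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EwsbenchError):
    """A definition, config object, or parameter set is invalid."""


class MissingDataError(EwsbenchError):
    """A required field is absent where completeness is a precondition."""


class InvalidRecordError(EwsbenchError):
    """A record violates a physiologic-domain invariant."""


class SchemaError(EwsbenchError):
    """An input table does not match the documented header/schema."""


class EmptyCohortError(EwsbenchError):
    """An operation that needs at least one record received none."""


class UndefinedMetricError(EwsbenchError):
    """A metric is undefined for the given inputs (e.g. single-class AUROC)."""


class PairingError(EwsbenchError):
    """Paired inputs have mismatched lengths or indexing."""


class FitError(EwsbenchError):
    """A model fit cannot be performed (too few points, single class, ...)."""
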