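"""Exception hierarchy shared across the pipeline."""


class FdmoscreenError(Exception):
    """Base class for all package errors."""


class FormatError(FdmoscreenError):
    """Input file could not be parsed in the expected format."""


class EmptyStructureError(FdmoscreenError):
    """A structure contained no usable atoms."""


class ConsistencyError(FdmoscreenError):
    """Poses in an ensemble disagree on atom names or ordering."""


class MissingFieldError(FdmoscreenError):
    """A required field (e.g. a pose energy) is absent."""


class DegenerateGeometryError(FdmoscreenError):
    """Geometry is ill-conditioned (collinear ring atoms, zero-length vectors)."""


class DomainError(FdmoscreenError):
    """A scalar argument lies outside its mathematical domain."""


class LookupError_(FdmoscreenError):
    """A named atom, residue or sequence could not be resolved."""


class DegenerateFitError(FdmoscreenError):
    """A model fit is impossible (single-class labels, rank deficiency)."""


class CollinearityError(DegenerateFitError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear descriptors: {self.columns}")


class ConfigError(FdmoscreenError):
    """Invalid configuration (separability violated, no backend available...)."""
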