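"""Exception hierarchy shared by all pipeline stages."""


class ModqtlError(Exception):
    """Base class for all data and configuration errors raised by modqtl."""


class ConfigError(ModqtlError):
    """Invalid or inconsistent configuration."""


class SchemaError(ModqtlError):
    """A table on disk does not match its declared column schema."""


class AllMissingError(ModqtlError):
    """A genotype vector contains no observed calls."""


class EmptyAfterQcError(ModqtlError):
    """Quality control removed every sample (or every SNP)."""


class DesignError(ModqtlError):
    """Covariate design matrix is rank deficient or has too few rows."""


class ZeroVarianceError(ModqtlError):
    """A probe with zero variance entered a correlation-based computation."""


class InputError(ModqtlError):
    """Malformed numeric input (e.g. a non-symmetric adjacency matrix)."""


class MonomorphicError(ModqtlError):
    """Genotype vector has fewer than two observed levels in complete cases."""


class AlignmentError(ModqtlError):
    """Sample identifiers disagree between tables that must be aligned."""


class EmptyInputError(ModqtlError):
    """An operation requiring at least one value received an empty input."""


class EmptyModuleError(ModqtlError):
    """A per-module operation received a module with no members."""


class InsufficientDataError(ModqtlError):
    """Too few complete observations for the requested statistic."""


class MissingReferenceError(ModqtlError):
    """A qPCR replicate lacks a measurement for a reference gene."""


class GroupMissingError(ModqtlError):
    """The Ct table lacks a required treatment or control group."""


class InsufficientReplicatesError(ModqtlError):
    """Fewer than two replicates per group for a t-test."""
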