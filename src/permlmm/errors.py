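"""Exception hierarchy shared across the package."""


class PermLMMError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PermLMMError):
    """Input file could not be parsed as the stated format."""


class EmptyInputError(PermLMMError):
    """File parsed but contained zero variants or zero samples."""


class ColumnNotFoundError(PermLMMError):
    """A requested phenotype or covariate column is absent."""


class DuplicateSampleError(PermLMMError):
    """Sample identifiers are not unique."""


class InsufficientSamplesError(PermLMMError):
    """Too few samples remain after alignment and missing-data exclusion."""


class FormulaError(PermLMMError):
    """Model formula could not be parsed in the supported dialect."""


class CollinearityError(PermLMMError):
    """A design matrix that must be full rank is rank deficient."""


class NestingError(PermLMMError):
    """The null model is not nested within the full model."""


class KernelError(PermLMMError):
    """A relatedness kernel is invalid (empty, non-symmetric or non-PSD)."""


class DegeneratePhenotypeError(PermLMMError):
    """Phenotype has zero variance; variance components are undefined."""


class ProjectorError(PermLMMError):
    """Residual-projector eigenvalues do not cluster at {0, 1}."""


class NoValidTestError(PermLMMError):
    """Every variant in a scan was degenerate; no p-value exists."""


class ConfigError(PermLMMError):
    """A simulation or run configuration is internally inconsistent."""
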