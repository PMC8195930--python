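"""Exception hierarchy for repertoire ingestion and analysis."""


class TcrdynError(Exception):
    """Base class for all package-specific errors."""


class ClonotypeFormatError(TcrdynError):
    """A clonotype table is malformed (e.g. a mandatory column is missing)."""


class DegenerateSampleError(TcrdynError):
    """A sample cannot support the requested computation (e.g. zero productive reads)."""


class AmbiguousSampleError(TcrdynError):
    """More than one sample maps to the same (patient, timepoint)."""


class UndefinedMetricError(TcrdynError):
    """A metric is mathematically undefined for the given input (e.g. clonality with R <= 1)."""


class ValidationError(TcrdynError):
    """Input values violate a precondition."""


class ConvergenceError(TcrdynError):
    """A model fit failed to converge (monotone likelihood / complete separation)."""
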