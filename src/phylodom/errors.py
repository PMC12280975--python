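"""Exception hierarchy shared across the package."""


class PhylodomError(Exception):
    """Base class for all package-specific errors."""


class NewickFormatError(PhylodomError):
    """Raised when a newick/nexus string cannot be parsed."""


class TreeValidationError(PhylodomError):
    """Raised when a parsed tree violates an invariant (duplicate tips,
    negative branch lengths, fewer than two tips)."""


class TaxonLookupError(PhylodomError, KeyError):
    """Raised when requested taxa are absent from a tree or covariance."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"taxa not found: {', '.join(self.missing)}")


class DegenerateTreeError(PhylodomError):
    """Raised when a tree yields an unusable covariance (e.g. zero depth)."""


class ClassificationError(PhylodomError):
    """Raised when a record carries no usable dominance information."""


class UndefinedMeasureError(PhylodomError):
    """Raised when a quantity (win proportion, contest mix, dyad fraction)
    is undefined for the given counts."""


class AggregationError(PhylodomError):
    """Raised when group records cannot be combined into one population."""


class StandardizationError(PhylodomError):
    """Raised for zero-variance or too-short predictor vectors."""


class DataValidationError(PhylodomError):
    """Raised when a data table violates the documented schema."""


class SampleSizeError(PhylodomError):
    """Raised when too few observations remain for an analysis."""


class DegenerateTraitError(PhylodomError):
    """Raised when a trait vector is constant (no signal can be estimated)."""


class LinearAlgebraError(PhylodomError):
    """Raised when a covariance matrix cannot be factorized."""


class ConvergenceError(PhylodomError):
    """Raised when an MCMC fit fails its convergence gate.

    Carries the offending diagnostics so callers can report them.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(PhylodomError):
    """Raised for invalid run configuration."""
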