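"""Exception hierarchy shared across the package.

Numerical-domain problems (non-positive catches under a log, degenerate
standards, singular designs) are hard errors on purpose: silently flooring a
quantum catch or a reflectance standard corrupts every JND computed downstream.
"""


class AposignalError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(AposignalError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedHueError(AposignalError, ZeroDivisionError):
    """Hue opponency ratio undefined (SW + MW catch is zero)."""


class DegenerateStandardsError(AposignalError, ValueError):
    """Grey-standard means equal or inverted; normalization impossible."""


class EmptyRegionError(AposignalError, ValueError):
    """A requested labelled region contains no pixels."""


class NewickParseError(AposignalError, ValueError):
    """Malformed Newick input."""


class TreeMismatchError(AposignalError, KeyError):
    """Species present in the data are missing from the tree (or vice versa)."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"species missing from tree: {', '.join(self.missing)}")


class CovarianceError(AposignalError, ValueError):
    """Phylogenetic covariance matrix is not positive definite."""


class RankDeficiencyError(AposignalError, ValueError):
    """Design matrix is rank deficient under the GLS inner product."""


class TransformDomainError(AposignalError, ValueError):
    """A log/sqrt transformation was requested on out-of-domain values."""


class InsufficientSpeciesError(AposignalError, ValueError):
    """Fewer species than the analysis requires."""


class InsufficientDataError(AposignalError, ValueError):
    """Too few individuals for a within-species regression."""


class InsufficientDfError(AposignalError, ValueError):
    """Model is saturated: no residual degrees of freedom."""


class ValidationError(AposignalError, ValueError):
    """Input table failed schema validation; carries the full offender list."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("traits table validation failed:\n  - " + "\n  - ".join(self.problems))
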