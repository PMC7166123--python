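"""Exception hierarchy shared across the package."""


class MainseqError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MainseqError, ValueError):
    """Invalid parameters, malformed input files, or violated invariants."""


class DegenerateThresholdError(MainseqError):
    """Median-based velocity dispersion is zero: thresholds would admit everything."""


class DegenerateLikelihoodError(MainseqError):
    """Zero residual sum of squares: the Gaussian likelihood is unbounded."""


class ConvergenceError(MainseqError):
    """Nonlinear least squares failed to converge within the restart budget.

    Carries the best iterate found so the caller can inspect it.
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result
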