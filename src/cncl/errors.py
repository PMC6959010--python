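"""Exception types raised across the package.

Every typed failure mode gets its own class so callers can distinguish
bad input files from degenerate statistics from optimizer failures.
"""


class CnclError(Exception):
    """Base class for all package errors."""


class ExpressionParseError(CnclError):
    """Malformed expression table (ragged rows, duplicate ids, non-numeric cells)."""


class ValidationError(CnclError):
    """Invalid configuration or input dimensions."""


class MissingGenesError(CnclError):
    """Signature genes absent from a matrix; carries the missing ids."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"signature genes missing from matrix: {', '.join(self.missing)}")


class EmptySignatureError(CnclError):
    """Signature derivation produced no genes (e.g. disjoint feature spaces)."""


class DegenerateInputError(CnclError):
    """Input is constant/tied where the statistic is undefined (e.g. cluster-mean tie)."""


class FitFailureError(CnclError):
    """No dose-response model converged."""


class ConvergenceError(CnclError):
    """Survival regression failed to converge (e.g. separation)."""
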