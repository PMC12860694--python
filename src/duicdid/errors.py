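"""Exception hierarchy for the pipeline.

Every error a stage can raise derives from :class:`DuicDidError` so the CLI
can map any failure to a nonzero exit with a single handler.
"""


class DuicDidError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DuicDidError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class UndefinedRateError(DuicDidError, ZeroDivisionError):
    """A rate was requested with a zero denominator."""


class RecodeError(DuicDidError, ValueError):
    """A covariate level is outside the known coding scheme."""


class DegenerateCellError(DuicDidError, ValueError):
    """A post-stratification cell has positive target share but no sample rows."""


class RakingConvergenceError(DuicDidError, RuntimeError):
    """Iterative proportional fitting failed to reach tolerance."""


class DegenerateTableError(DuicDidError, ValueError):
    """A contingency table has a zero marginal."""


class SeparationError(DuicDidError, RuntimeError):
    """Logistic coefficients diverged (perfect or quasi-perfect separation)."""


class AliasingError(DuicDidError, ValueError):
    """Design matrix is rank deficient; the message names aliased columns."""


class BracketError(DuicDidError, ValueError):
    """Power at the bracket ends does not straddle the target power."""


class UndefinedShareError(DuicDidError, ZeroDivisionError):
    """Episode shares are undefined because the episode total is zero."""


class IncompleteRecordError(DuicDidError, ValueError):
    """A categorical episode count of 'more than 15' lacks its exact value."""
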