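"""Exception hierarchy for the mireqtl pipeline.

All errors derive from :class:`MirEqtlError` so callers can catch the
package's failures with a single except clause while still letting the
more specific classes drive control flow (e.g. an untestable SNP is a
per-SNP signal, not a fatal condition).
"""


class MirEqtlError(Exception):
    """Base class for all mireqtl errors."""


class ParseError(MirEqtlError, ValueError):
    """A tab-delimited input file violates its format contract."""


class ContractError(MirEqtlError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class ConfigurationError(MirEqtlError, ValueError):
    """A study-level configuration is unusable (e.g. empty sample intersection)."""


class DegenerateSampleError(MirEqtlError, ValueError):
    """A sample cannot be normalized (non-positive 75th percentile)."""


class DegenerateFitError(MirEqtlError, ArithmeticError):
    """A regression fit has (numerically) zero residual variance."""


class UntestableSnpError(MirEqtlError):
    """A SNP yields a constant genotype indicator and cannot be tested.

    Raised as a signal: scans catch it, log the reason and skip the SNP.
    """
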