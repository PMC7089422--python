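"""Exception hierarchy for lipidmr.

All package-specific failures derive from :class:`LipidMRError` so callers
can catch one base class at pipeline boundaries.
"""


class LipidMRError(Exception):
    """Base class for all lipidmr errors."""


class ConfigurationError(LipidMRError, ValueError):
    """An invalid simulation or analysis configuration."""


class DataError(LipidMRError, ValueError):
    """Malformed or inconsistent input data (summary statistics, LD, alleles)."""


class EstimationError(LipidMRError, ValueError):
    """An estimator was called on input it cannot handle (too few SNPs,
    rank-deficient exposure matrix, zero exposure effect, ...)."""
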