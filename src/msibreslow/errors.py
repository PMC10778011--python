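"""Exception hierarchy shared across the pipeline stages."""


class MsiBreslowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MsiBreslowError, ValueError):
    """Invalid simulation or threshold parameters."""


class MaskError(MsiBreslowError, ValueError):
    """Region-of-interest mask violates a precondition (empty, fragmented, too small)."""


class InputError(MsiBreslowError, ValueError):
    """Mismatched or malformed inputs (dimension mismatch, length mismatch)."""


class FormatError(MsiBreslowError, ValueError):
    """A file on disk is not in the expected format."""


class GenerationError(MsiBreslowError, ValueError):
    """Synthetic lesion cannot be rendered under the requested geometry."""


class FitError(MsiBreslowError, ValueError):
    """Regression design matrix is rank deficient."""


class UndefinedMetricError(MsiBreslowError, ValueError):
    """A diagnostic metric is undefined for the given counts."""


class ReconciliationError(MsiBreslowError, ValueError):
    """Reconstructed confusion marginals are internally inconsistent."""
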