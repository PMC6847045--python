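"""Exception hierarchy shared across the package."""


class PdcovarError(Exception):
    """Base class for all pdcovar errors."""


class AlignmentShapeError(PdcovarError):
    """Rows of an alignment have unequal length, or the alignment is empty."""


class AlphabetError(PdcovarError):
    """A sequence contains symbols outside the expected alphabet."""


class TrimmingError(PdcovarError):
    """A target site does not provide enough flanking bases for trimming."""


class PairingError(PdcovarError):
    """Protein members and target sites cannot be matched one-to-one."""


class InsufficientDataError(PdcovarError):
    """Too few usable (non-gap) observations to compute a statistic."""


class DegenerateAlignmentError(PdcovarError):
    """Alignment carries no information for the requested correction."""


class StandardizationError(PdcovarError):
    """Score vector has zero spread and cannot be Z-standardized."""


class ConfigurationError(PdcovarError):
    """Invalid run configuration (barcode maps, simulation configs, ...)."""


class TransformError(PdcovarError):
    """Count vector cannot be CLR-transformed."""


class FitError(PdcovarError):
    """Regression input does not support a fit (e.g. <2 distinct times)."""


class NormalizationError(PdcovarError):
    """Reference slope is zero; relative rates are undefined."""
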