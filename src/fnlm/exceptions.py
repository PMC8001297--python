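"""Exception hierarchy for the fnlm package."""


class FNLMError(Exception):
    """Base class for all package errors."""


class FormatError(FNLMError):
    """Unsupported image sample format or file layout."""


class ParameterError(FNLMError, ValueError):
    """Invalid filter or sweep parameters."""


class DimensionError(FNLMError, ValueError):
    """Shape/ROI mismatch or an input too small for the operation."""


class UnsupportedModeError(FNLMError):
    """A mode combination the algorithm cannot honour."""


class UndefinedMetricError(FNLMError):
    """A metric whose definition breaks down on the given input."""


class DegenerateInputError(FNLMError):
    """Statistical input with no usable spread (e.g. all samples equal)."""


class InsufficientDataError(FNLMError):
    """Not enough samples/patches to fit the requested model."""


class PlacementError(FNLMError):
    """Phantom nuclei could not be placed within the attempt budget."""
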