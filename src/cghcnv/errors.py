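class CghCnvError(Exception):
    """Base class for all package errors."""


class ConfigError(CghCnvError):
    """Invalid configuration or parameter value."""


class StructuralError(CghCnvError):
    """Malformed input table (wrong columns, unsorted, out of bounds)."""


class PlacementError(CghCnvError):
    """An interval could not be placed on the genome."""


class PreprocessError(CghCnvError):
    """Quality control or normalization could not proceed."""


class SegmentationError(CghCnvError):
    """Segmentation preconditions violated."""
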