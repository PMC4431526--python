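"""Exception hierarchy for the screen pipeline."""


class WormscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(WormscreenError):
    """A table is missing a mandatory column or has an unrecognized header."""


class DuplicateWellError(WormscreenError):
    """The same (plate, well, strain, replicate) key appears more than once."""


class LayoutError(WormscreenError):
    """A plate layout is structurally invalid (not merely non-conforming)."""


class CalibrationError(WormscreenError):
    """Cut-off calibration is impossible (no usable control ratios)."""


class GeneMappingError(WormscreenError):
    """A clone cannot be mapped to a gene identifier."""


class ConfigurationError(WormscreenError):
    """A simulation or pipeline configuration violates its invariants."""
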