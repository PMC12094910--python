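"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`OispipeError` so that the CLI can
abort with a stage-tagged message instead of a raw traceback.
"""


class OispipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(OispipeError):
    """Invalid or inconsistent configuration (bad windows, mismatched tables)."""


class InputError(OispipeError):
    """Malformed or unusable input data (non-positive intensities, no triggers)."""


class NumericalError(OispipeError):
    """Numerically unusable problem (ill-conditioned unmixing design)."""
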