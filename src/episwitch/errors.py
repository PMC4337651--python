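"""Package-specific exception types."""


class ParameterError(ValueError):
    """A parameter is outside its admissible range."""


class DegeneratePlateError(ValueError):
    """Half-sector estimator denominator (total - fully green) is not positive."""


class PlacementError(RuntimeError):
    """Non-overlapping placement failed after bounded retries."""


class UnsupportedTimingModelError(ValueError):
    """Operation requires a cell_cycle-mode simulation."""


class ConfigError(ValueError):
    """Run configuration failed validation; message carries the field path."""
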