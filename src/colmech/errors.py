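"""Exception types shared by all colmech modules."""


class ColmechError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ColmechError, ValueError):
    """A configuration object violates its invariants."""


class StructuralError(ColmechError, ValueError):
    """Two data structures that must be consistent are not."""


class ValidationError(ColmechError, ValueError):
    """An input value is outside its admissible domain."""
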