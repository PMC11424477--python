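"""Exception types shared across the package."""


class PhosphokinError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PhosphokinError, ValueError):
    """A function was called with invalid parameter values."""


class ParseError(PhosphokinError, ValueError):
    """An input file or field could not be parsed."""


class ConfigError(PhosphokinError, ValueError):
    """A pipeline configuration is invalid.

    Carries the full list of violations so callers can report every
    problem at once rather than the first one hit.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations))
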