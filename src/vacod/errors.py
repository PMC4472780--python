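"""Exception hierarchy shared across the package."""


class VacodError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VacodError):
    """Malformed input file: missing columns, bad cell values, duplicate ids."""


class VocabularyError(VacodError):
    """A cause label used outside its age group's vocabulary."""


class OutOfRangeError(VacodError):
    """A numeric value outside its documented domain."""


class ConfigError(VacodError):
    """Invalid configuration: non-stochastic kernel, CSMF not summing to 1, ..."""


class DegenerateMarginalsError(VacodError):
    """Both raters constant on a single label: chance agreement is 1 and kappa undefined."""


class UniverseMismatchError(VacodError):
    """Two per-record mappings do not cover the same record ids."""

    def __init__(self, message: str, missing: tuple = ()) -> None:
        super().__init__(message)
        self.missing = tuple(missing)
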