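"""Exception hierarchy used across the package."""


class TriprotError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TriprotError):
    """A parameter value is outside its legal range."""


class DataFormatError(TriprotError):
    """An input file violates the expected dialect (duplicate IDs, bad values)."""


class CohortStructureError(TriprotError):
    """The cohort lacks the sample structure an operation requires."""


class DegenerateDataError(TriprotError):
    """The data admit no well-defined answer (zero variance, empty groups)."""
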