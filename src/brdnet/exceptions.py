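"""Typed error signals shared across brdnet modules."""


class BrdnetError(Exception):
    """Base class for all package-specific errors."""


class DialectError(BrdnetError, ValueError):
    """An interaction table does not conform to the requested dialect."""


class DegenerateTableError(BrdnetError, ValueError):
    """A contingency table has an empty margin; the chi-square test is undefined."""


class FitUndefinedError(BrdnetError, ValueError):
    """A distribution fit is undefined for the given sample (e.g. constant degrees)."""


class ConfigError(BrdnetError, ValueError):
    """Pipeline configuration failed validation; message lists every violation."""
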