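"""Exception hierarchy shared across the toolkit."""


class HlaETypingError(Exception):
    """Base class for all toolkit errors."""


class InputError(HlaETypingError, ValueError):
    """Malformed or inconsistent user input (files, sequences, curves)."""


class AlignmentError(InputError):
    """Reference sequences are not a pre-aligned equal-length block."""


class SiteConfigError(InputError):
    """A named site does not fit the loaded reference block."""


class DuplicateAlleleError(InputError):
    """Two reference records share one allele id."""


class UnknownAlleleError(HlaETypingError, KeyError):
    """Lookup of an allele id or site label that is not in the database."""


class StatisticError(HlaETypingError, ValueError):
    """A statistic is undefined for the given counts (zero margin/cell)."""
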