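"""Exception hierarchy.

All package errors derive from :class:`EgressError`; most are also
``ValueError`` subclasses so callers who do not care about the distinction
can catch the builtin.
"""


class EgressError(Exception):
    """Base class for all antegress errors."""


class FormatError(EgressError, ValueError):
    """An input table is structurally invalid (e.g. a required column is missing)."""


class ParseError(FormatError):
    """A cell could not be parsed (e.g. a non-numeric escape time)."""


class ValidationError(EgressError, ValueError):
    """Data violates a domain invariant (e.g. an unknown condition label)."""


class ConfigurationError(EgressError, ValueError):
    """A configuration value is missing or inconsistent."""


class DomainError(EgressError, ValueError):
    """An operation was applied outside its domain (e.g. mean of no intervals)."""


class SingularityError(DomainError, ZeroDivisionError):
    """Group flow rate requested for a group whose evacuation time is zero.

    A two-member group whose ants exit simultaneously has t_S = 0 and an
    infinite Q_S; such groups are excluded from statistics rather than
    assigned a value.
    """
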