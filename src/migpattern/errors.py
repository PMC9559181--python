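"""Exception hierarchy for the migpattern pipeline.

All pipeline errors derive from :class:`MigpatternError` so callers can catch
one base class; the subclasses distinguish malformed files, inconsistent
data, and invalid parameter choices.
"""


class MigpatternError(Exception):
    """Base class for all migpattern errors."""


class FormatError(MigpatternError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class IntegrityError(MigpatternError):
    """Data violates a structural invariant (duplicates, gaps, mismatched sets)."""


class ParameterError(MigpatternError, ValueError):
    """A parameter value is outside its valid domain."""


class DomainError(MigpatternError, ValueError):
    """An operation was applied to an input outside its mathematical domain."""
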