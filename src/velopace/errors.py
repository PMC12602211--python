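"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/format errors -> 1,
numerical errors -> 2.
"""


class VelopaceError(Exception):
    """Base class for all package errors."""


class ValidationError(VelopaceError):
    """An input value violates a documented precondition or invariant."""


class CourseFormatError(VelopaceError):
    """A course file is structurally malformed (e.g. missing columns)."""


class NumericalError(VelopaceError):
    """A numerical routine failed to converge or bracket a root."""
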