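"""Exception hierarchy with CLI exit codes.

Exit-code convention: 0 success, 2 validation/format, 3 I/O, 4 statistical
degeneracy.
"""


class SearchShareError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(SearchShareError):
    """Input file does not conform to the expected dialect."""

    exit_code = 2


class ValidationError(SearchShareError):
    """Data or configuration violates a documented invariant."""

    exit_code = 2


class InputOutputError(SearchShareError):
    """A file could not be read or written."""

    exit_code = 3


class DegeneracyError(SearchShareError):
    """A statistical operation received a degenerate design (empty group,
    too few observations, cutoff outside the observed span)."""

    exit_code = 4
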