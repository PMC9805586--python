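"""Exception hierarchy shared across the package.

Split into two families so the CLI can map them to distinct exit codes:
format/parse problems (the file could not be understood) versus validation
problems (the file was understood but its content is inconsistent with the
genome, the annotation or another input).
"""


class LocalGreatError(Exception):
    """Base class for all package errors."""


class FormatError(LocalGreatError):
    """A file could not be parsed (malformed line, wrong column count...)."""


class InputError(LocalGreatError):
    """Parsed input violates a precondition (bad counts, bad parameters)."""


class AnnotationMismatchError(InputError):
    """A record refers to a chromosome unknown to the governing genome."""


class SubsetViolationError(InputError):
    """Foreground regions are not an exact subset of the background regions."""


class ConsistencyError(LocalGreatError):
    """Internal invariant violated; indicates a bug, not a user error."""
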