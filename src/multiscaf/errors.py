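"""Exception hierarchy.

``UserInputError`` covers everything a user can fix (bad files, bad
parameters); the CLI maps it to exit code 1. Anything else escaping the
pipeline is an internal error (exit code 2).
"""


class MultiscafError(Exception):
    """Base class for all package errors."""


class UserInputError(MultiscafError):
    """Invalid user-supplied input: files, parameters, id collisions."""


class FormatError(UserInputError):
    """A file does not conform to its expected on-disk format."""
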