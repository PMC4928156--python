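"""Exception hierarchy shared by the library and the command line.

``InputError`` maps to exit code 2 (malformed or missing input data);
``ValidationError`` maps to exit code 3 (inputs parsed but failed a
consistency check, e.g. a wild-type residue that does not match the
sequence).
"""


class StabilisError(Exception):
    """Base class for package errors."""

    exit_code = 1


class InputError(StabilisError):
    exit_code = 2


class ValidationError(StabilisError):
    exit_code = 3
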