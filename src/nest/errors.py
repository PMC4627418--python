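"""Exception hierarchy shared across the package.

Validation problems (bad inputs, contract violations) and parse problems
are kept distinct from plain I/O errors so the command-line layer can map
them onto stable exit codes.
"""


class NestError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NestError, ValueError):
    """Input violates a documented contract (bad weight, empty overlap, ...)."""


class ParseError(ValidationError):
    """A text input could not be parsed; message names the offending line."""


class RewiringError(NestError, RuntimeError):
    """Stub rewiring could not reconnect enough edges within the restart budget."""
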