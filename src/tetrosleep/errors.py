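"""Exception hierarchy shared across the package.

Each error class carries the CLI exit code used by ``tetrosleep.cli``:
invalid input -> 2, file/format problems -> 3, empty feature selection -> 4.
"""


class TetroSleepError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidInputError(TetroSleepError):
    """An input violates a documented precondition (shape, length, finiteness)."""

    exit_code = 2


class FormatError(TetroSleepError):
    """A file could not be parsed or is internally inconsistent."""

    exit_code = 3


class ChannelError(FormatError):
    """A requested EDF channel is absent and cannot be derived."""

    exit_code = 3


class EmptySelectionError(TetroSleepError):
    """A selection stage removed every feature."""

    exit_code = 4
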