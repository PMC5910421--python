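"""Exception hierarchy shared by all stages.

Exit-code contract for the CLI: configuration problems exit 2,
malformed input files exit 3, everything else is a bug.
"""


class CisTransError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(CisTransError):
    """Invalid parameters, options or study configuration."""

    exit_code = 2


class InputFormatError(CisTransError):
    """A data file violates its schema; message names file/line/column."""

    exit_code = 3
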