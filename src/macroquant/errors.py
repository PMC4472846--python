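"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: configuration errors exit 2, input errors
exit 3, anything else that escapes exits 4.
"""


class MacroquantError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ConfigurationError(MacroquantError):
    """Invalid or missing configuration (bad parameter, undeclared channel...)."""

    exit_code = 2


class InputError(MacroquantError):
    """Invalid input data (unreadable file, shape mismatch, empty sequence...)."""

    exit_code = 3


class GenerationError(MacroquantError):
    """Synthetic scene could not be generated under the requested constraints."""

    exit_code = 4
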