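"""Exception hierarchy shared across the package.

Two broad failure classes are distinguished so the command-line layer can
map them onto distinct exit codes: problems with a configuration object or
threshold (``ConfigurationError``) versus problems with the data handed to
an operation (``DataError``).
"""


class ExoantigenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ExoantigenError):
    """An invalid parameter, threshold, or simulation configuration."""


class DataError(ExoantigenError):
    """Malformed, empty, or inconsistent input data."""
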