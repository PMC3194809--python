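"""Exception hierarchy shared by the library and the CLI.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; plain :class:`ValueError` raised by library internals is
treated as a configuration problem.
"""


class PeakconcordError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PeakconcordError, ValueError):
    """Invalid configuration: bad parameter values, unknown preset names."""


class DataError(PeakconcordError, ValueError):
    """Structurally invalid data: mismatched grids, empty spectra,
    replicate bookkeeping errors."""
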