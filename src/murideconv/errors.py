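"""Exception hierarchy shared by all modules.

The CLI maps these onto process exit codes: :class:`FormatError` and
:class:`ValidationError` → 2, :class:`CoverageError` → 3,
:class:`ConfigError` → 4.
"""


class MurideconvError(Exception):
    """Base class for all package errors."""


class FormatError(MurideconvError):
    """A file could not be parsed as the expected on-disk format."""


class ValidationError(MurideconvError):
    """A container invariant is violated (negative TPM, duplicate ids, ...)."""


class CoverageError(MurideconvError):
    """Too few signature/marker genes are present in the expression matrix."""


class ConfigError(MurideconvError):
    """An invalid option, unknown method or resource name."""
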