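"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`DomainError`/:class:`AssayError`
are data errors (exit 1); :class:`ConfigError`/:class:`InputError` are
configuration/schema errors (exit 2).
"""


class EnzvecError(Exception):
    """Base class for all package errors."""


class DomainError(EnzvecError, ValueError):
    """A value violates a mathematical precondition (e.g. zero enzyme group)."""


class AssayError(EnzvecError):
    """A plate reduction step cannot proceed (e.g. fully quenched standard)."""


class ConfigError(EnzvecError):
    """A configuration is invalid or infeasible."""


class InputError(EnzvecError):
    """An input table violates its schema (bad roles, duplicates, NaNs)."""
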