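"""Exception hierarchy for covdet.

All validation failures derive from :class:`CovdetError` so callers can
catch the package's errors with one clause; the leaf classes also derive
from the matching built-in (``ValueError`` / ``RuntimeError``) so code that
does not know about covdet still behaves sensibly.
"""


class CovdetError(Exception):
    """Base class for all covdet errors."""


class InvalidArgumentError(CovdetError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(CovdetError, ValueError):
    """Two tables that must share a schema do not."""


class DegenerateLabelError(CovdetError, ValueError):
    """A training set contains a single class."""


class InvalidStateError(CovdetError, RuntimeError):
    """An internal state invariant was violated (e.g. all-zero weights)."""


class ConfigError(CovdetError, ValueError):
    """A run configuration is invalid or references missing inputs."""
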