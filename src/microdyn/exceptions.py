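"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`MicrodynError`,
so callers can catch one type. The subclasses mirror the distinct failure
contracts of the analysis operations (degenerate feature vs. undefined test,
etc.) rather than the module they live in.
"""


class MicrodynError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MicrodynError, ValueError):
    """A caller-supplied argument violates a precondition."""


class InvalidInputError(MicrodynError, ValueError):
    """Input data violates a contract (e.g. negative value under log10)."""


class DegenerateFeatureError(MicrodynError, ValueError):
    """A feature cannot be standardized (zero central spread, too few values)."""


class DegenerateInputError(MicrodynError, ValueError):
    """A regression input has no variance."""


class UndefinedTestError(MicrodynError, ValueError):
    """A statistical test is undefined for the given data (e.g. no nonzero pairs)."""


class UndefinedInputError(MicrodynError, ValueError):
    """A quantity is undefined for the given input (e.g. diversity of all zeros)."""


class ConfigError(MicrodynError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
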