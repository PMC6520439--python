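"""Exception hierarchy shared across the package."""


class MetacazError(Exception):
    """Base class for all package-level errors."""


class TaxonomyError(MetacazError):
    """Structural problem in a taxonomy tree (cycle, missing parent, bad rank)."""


class DataError(MetacazError):
    """Malformed or inconsistent input data (bad EC string, unknown contig, ...)."""


class DegenerateInputError(MetacazError):
    """Input that is formally valid but has no meaningful answer (all-zero rows, ...)."""


class DependencyError(MetacazError):
    """A pipeline stage was requested before its upstream outputs exist."""


class ConfigError(MetacazError):
    """Invalid run configuration."""
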