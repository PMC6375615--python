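"""Exception hierarchy shared across the package."""


class StochDEAError(Exception):
    """Base class for all package errors."""


class FormatError(StochDEAError):
    """Malformed input file (duplicate names, bad header, wrong layout)."""


class ValidationError(StochDEAError):
    """Data violates a model invariant (negative rate, empty variable side)."""


class ResolutionError(StochDEAError):
    """A name refers to a DMU, variable or cell that does not exist."""


class ConfigurationError(StochDEAError):
    """An engine configuration is internally inconsistent."""


class SolverError(StochDEAError):
    """The LP solver failed or returned an unusable status."""
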