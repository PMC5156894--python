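"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError-family failures map to
exit status 2 (bad inputs), everything else to 1 (runtime failure).
"""


class AeroscopeError(Exception):
    """Base class for all package errors."""


class FormatError(AeroscopeError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class ValidationError(AeroscopeError):
    """Data violates a declared invariant (units, monotonicity, enum tokens)."""


class ConfigError(AeroscopeError):
    """Run configuration is unparseable, has unknown keys, or out-of-range values."""


class EstimationError(AeroscopeError):
    """A fit cannot be computed (too few points, zero variance, rank deficiency)."""


class SimulationError(AeroscopeError):
    """A simulation config drives the system into an unphysical state."""
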