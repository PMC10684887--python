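"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: configuration problems -> 2,
data problems -> 3, numerical/solver problems -> 4.
"""


class RepsampleError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RepsampleError):
    """Invalid configuration or parameters."""

    exit_code = 2


class SchemaError(RepsampleError):
    """Input data does not match the declared schema."""

    exit_code = 3


class EmptyDataError(RepsampleError):
    """A dataset is empty (possibly after the missing-value filter)."""

    exit_code = 3


class DegenerateBandwidthError(RepsampleError):
    """The bandwidth heuristic produced a zero mean distance."""

    exit_code = 4


class DegenerateWeightsError(RepsampleError):
    """A weight vector sums to zero where positive mass is required."""

    exit_code = 4


class SolverError(RepsampleError):
    """The quadratic-program solver failed or returned an infeasible point."""

    exit_code = 4


class MetricError(RepsampleError):
    """A metric is undefined for the given inputs (e.g. single-class AUROC)."""

    exit_code = 3
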