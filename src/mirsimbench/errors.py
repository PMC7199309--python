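"""Exception hierarchy shared across the package."""


class MirSimBenchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirSimBenchError):
    """An invalid generator or run configuration."""


class InputError(MirSimBenchError):
    """Malformed or inconsistent input data."""


class ComputationError(MirSimBenchError):
    """A numeric contract violated during computation."""


class EvaluationError(MirSimBenchError):
    """No evaluable test case, or an ill-posed evaluation request."""
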