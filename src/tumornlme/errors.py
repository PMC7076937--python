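"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Inconsistent model/solver/design configuration (wrong state length, unknown model id, ...)."""


class DomainError(ValueError):
    """Inputs outside the mathematical domain of an operation (non-finite values, width > length, ...)."""


class SolverError(RuntimeError):
    """Numerical integration failure; carries a diagnostic message."""
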