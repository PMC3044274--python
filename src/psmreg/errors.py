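"""Exception hierarchy."""


class PsmRegError(Exception):
    """Base class for all psmreg errors."""


class ConfigError(PsmRegError):
    """Invalid configuration: missing columns, bad parameter values."""


class ContractError(PsmRegError):
    """An internal precondition was violated (caller bug)."""


class RowError(PsmRegError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ConvergenceError(PsmRegError):
    """Iterative solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations
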