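"""Exception hierarchy for lotcrt."""


class LotCrtError(Exception):
    """Base class for all package errors."""


class ParameterError(LotCrtError, ValueError):
    """Invalid or geometrically infeasible parameters."""


class FormatError(LotCrtError, ValueError):
    """Malformed or incomplete mesh / tree files."""


class CalibrationError(LotCrtError, RuntimeError):
    """Fascicle conduction-velocity calibration cannot satisfy its constraints."""


class SolverError(LotCrtError, RuntimeError):
    """Invalid solver input (bad sources, non-unit fibers, zero-speed source region)."""


class ConvergenceError(LotCrtError, RuntimeError):
    """Coupled tree/tissue iteration hit the iteration cap before its fixed point."""
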