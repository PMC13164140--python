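"""Exception hierarchy for lipoxkin."""


class LipoxkinError(Exception):
    """Base class for all package errors."""


class MechanismError(LipoxkinError):
    """Invalid mechanism definition (species, stoichiometry, composition)."""


class MechanismParseError(MechanismError):
    """Malformed mechanism text. Carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ThermoRangeError(LipoxkinError):
    """Temperature outside the valid range of a thermodynamic record."""


class IntegrationError(LipoxkinError):
    """Stiff ODE integration failed. Carries the failing time if known."""

    def __init__(self, message: str, t_fail: float | None = None):
        self.t_fail = t_fail
        super().__init__(message)


class AnalysisError(LipoxkinError):
    """Undefined derived metric (zero baseline, degenerate input)."""


class ValidationError(LipoxkinError):
    """Simulated/experimental pairing or metric computation failed."""
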