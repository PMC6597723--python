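"""Exception hierarchy for the analysis pipeline."""


class CPRAnalysisError(Exception):
    """Base class for all package errors."""


class PDBParseError(CPRAnalysisError):
    """A PDB record could not be parsed; message names the offending line."""


class TopologyError(CPRAnalysisError):
    """Models of a multi-model file disagree in atom count or ordering."""


class SelectionError(CPRAnalysisError):
    """An atom selection is invalid or resolves to no atoms."""


class ValidationError(CPRAnalysisError):
    """Input data violates a documented precondition."""


class DegenerateGeometryError(CPRAnalysisError):
    """Too few or collinear points for a rigid superposition."""


class PairingError(CPRAnalysisError):
    """Frame/reference atom pairing for superposition is incomplete."""


class IntegrationError(CPRAnalysisError):
    """The toy integrator produced a non-finite energy."""


class ConvergenceError(CPRAnalysisError):
    """Iterative alignment failed to converge."""


class StatisticsError(CPRAnalysisError):
    """A statistical estimate is undefined (e.g. zero variance)."""


class StageError(CPRAnalysisError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
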