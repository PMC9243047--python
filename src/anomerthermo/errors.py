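"""Typed exceptions shared across the pipeline."""


class AnomerThermoError(Exception):
    """Base class for package errors."""


class ParseError(AnomerThermoError):
    """Malformed text input (XYZ, Z-matrix, QC output)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateTorsionError(AnomerThermoError):
    """Collinear central bond: the torsion angle is undefined."""


class RingTorsionError(AnomerThermoError):
    """The central bond of a torsion lies inside a ring and cannot be rotated."""


class StoichiometryError(AnomerThermoError):
    """A reaction does not balance in elements or charge."""


class NotAMinimumError(AnomerThermoError):
    """A structure carries imaginary frequencies where a minimum is required."""


class EmptyEnsembleError(AnomerThermoError):
    """A Boltzmann operation was asked for on an empty conformer set."""


class DegeneratePlanError(AnomerThermoError):
    """A sampling plan with no rotatable dihedrals but more than one sample."""


class RegistryLookupError(AnomerThermoError, KeyError):
    """A species required by a reaction is absent from the registry."""


class PairingError(AnomerThermoError):
    """Two records that must match in species/phase/pathway do not."""


class ConstructionError(AnomerThermoError):
    """A synthetic-data spec cannot be realised (e.g. infeasible planted weight)."""


class SingularPairError(AnomerThermoError):
    """Two atoms closer than the hard-core cutoff of the surrogate potential."""


class PipelineStageError(AnomerThermoError):
    """A pipeline stage failed; names the stage and offending artifact."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
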