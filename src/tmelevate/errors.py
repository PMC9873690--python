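"""Exception types shared across the pipeline."""


class TmelevateError(Exception):
    """Base class for all package errors."""


class StructureFormatError(TmelevateError):
    """Input structure file could not be parsed."""


class ChainNotFoundError(TmelevateError, LookupError):
    """Requested chain is absent from the structure."""


class MissingResidueError(TmelevateError, LookupError):
    """Requested residues/atoms are absent from a model."""

    def __init__(self, missing, message=None):
        self.missing = sorted(missing)
        super().__init__(message or f"missing residues/atoms: {self.missing}")


class TopologyValidationError(TmelevateError):
    """Helix topology config violates its invariants."""


class AlignmentValidationError(TmelevateError):
    """Repeat alignment inconsistent with the declared topology."""


class DegenerateGeometryError(TmelevateError):
    """Numerical operation is ill-conditioned for this input."""


class ContractError(TmelevateError):
    """Operation preconditions violated."""
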