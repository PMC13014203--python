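"""Exception hierarchy shared across the package."""


class FibrilmodError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(FibrilmodError):
    """Topology is inconsistent with itself or with a trajectory."""


class FormatError(FibrilmodError):
    """An input file could not be parsed in any supported dialect."""


class QCUnavailableError(FibrilmodError):
    """Periodic-image QC requested on frames without box vectors."""


class EmptyEnsembleError(FibrilmodError):
    """An operation that needs frames received an empty ensemble."""


class IncompatibleMapsError(FibrilmodError):
    """Contact maps with different cutoffs/separations were combined."""


class ParameterError(FibrilmodError):
    """An analysis parameter violates its constraints (e.g. r_on >= r_off)."""


class NonFluctuatingError(FibrilmodError):
    """A contact-state series never switches, so no relaxation time exists."""


class EmptyStructureError(FibrilmodError):
    """A fibril file contains no usable protein chain."""


class GenerationError(FibrilmodError):
    """A synthetic structure design could not be realised geometrically."""


class SpecError(FibrilmodError):
    """A generator specification is internally inconsistent."""


class ValidationError(FibrilmodError):
    """A run manifest or configuration failed validation."""
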