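"""Exception hierarchy for sambrush."""


class SambrushError(Exception):
    """Base class for all sambrush errors."""


class ParseError(SambrushError):
    """A coordinate file line could not be parsed (message names the line)."""


class StructureError(SambrushError):
    """Inconsistent structure, e.g. atom counts differing between frames."""


class SelectionError(SambrushError):
    """An atom selection referenced something absent from the topology."""


class ChemistryError(SambrushError):
    """Unknown residue/linker unit, or a missing mass/radius."""


class PackingError(SambrushError):
    """Requested grafting density cannot be placed without clashes."""


class StabilityError(SambrushError):
    """Integrator step produced displacements larger than a bond length."""


class AnalysisError(SambrushError):
    """An analysis precondition failed (empty window, grid mismatch, ...)."""


class MatrixError(SambrushError):
    """A residue-pair energy matrix is missing a required entry."""
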