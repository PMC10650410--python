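"""Exception hierarchy for the hbpoly toolkit."""


class HbpolyError(Exception):
    """Base class for all hbpoly errors."""


class InfeasibleConstraints(HbpolyError):
    """Growth constraints cannot be satisfied by valence arithmetic."""


class GrowthExhausted(HbpolyError):
    """Retry budget spent without placing every monomer."""


class UnresolvedAttachment(HbpolyError):
    """A topology still carries open attachment points that cannot be capped."""


class ParseError(HbpolyError):
    """A SMILES or structure file failed to parse."""


class EmbeddingFailure(HbpolyError):
    """3D coordinate embedding failed after retries."""


class UnknownElement(HbpolyError):
    """An element symbol is not in the atomic-weight table."""


class MissingRadius(HbpolyError):
    """An element has no van der Waals radius entry."""


class OverlappingSolutes(HbpolyError):
    """Solute molecules overlap and cannot be solvated as given."""


class BoxTooSmall(HbpolyError):
    """The requested box cannot contain the solutes."""


class PlacementFailure(HbpolyError):
    """Random placement failed after the retry budget."""


class UnknownPreset(HbpolyError):
    """Drying-schedule preset name is not recognized."""


class EngineFailure(HbpolyError):
    """An MD engine backend failed during a stage."""

    def __init__(self, stage_index: int, message: str):
        self.stage_index = stage_index
        super().__init__(f"stage {stage_index}: {message}")


class DomainError(HbpolyError):
    """An input is outside the valid domain of an operation."""


class EmptySelection(HbpolyError):
    """An atom selection is empty where at least one atom is required."""
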