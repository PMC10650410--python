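"""Formulation bookkeeping: encapsulation efficiency, loading, planning.

Efficiency is the percentage of aimed drug molecules retained per polymer
molecule after formulation, rounded to the nearest integer percent.  The
formulation planner converts a target drug-per-polymer ratio into the stock
solution volume to pipette for a given polymer weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "EncapsulationRecord",
    "FormulationPlan",
    "efficiency",
    "plan_formulation",
    "loading_from_sim",
]


@dataclass(frozen=True)
class EncapsulationRecord:
    polymer: str
    drug: str
    aimed_per_polymer: int
    encapsulated_per_polymer: int
    efficiency_percent: int

    def __post_init__(self) -> None:
        if not 0 <= self.encapsulated_per_polymer <= self.aimed_per_polymer:
            raise DomainError("encapsulated count must lie in [0, aimed]")

    def to_row(self) -> dict:
        return {
            "polymer": self.polymer,
            "drug": self.drug,
            "aimed_per_polymer": self.aimed_per_polymer,
            "encapsulated_per_polymer": self.encapsulated_per_polymer,
            "efficiency_percent": self.efficiency_percent,
        }


@dataclass(frozen=True)
class FormulationPlan:
    polymer_mg: float
    polymer_mn: float
    drug: str
    drug_mw: float
    aimed_per_polymer: int
    stock_mg_per_ml: float
    stock_volume_ml: float


def efficiency(aimed: int, encapsulated: int) -> int:
    """Encapsulation efficiency in integer percent: round(100 x enc/aimed)."""
    if aimed < 1:
        raise DomainError("aimed must be >= 1")
    if not 0 <= encapsulated <= aimed:
        raise DomainError("encapsulated must lie in [0, aimed]")
    return int(round(100.0 * encapsulated / aimed))


def plan_formulation(
    polymer_mg: float,
    polymer_mn: float,
    aimed_per_polymer: int,
    drug_mw: float,
    stock_mg_per_ml: float = 5.0,
    drug: str = "",
) -> FormulationPlan:
    """Stock volume needed to reach an aimed drug-per-polymer ratio.

    volume (mL) = (polymer mg / Mn) x aimed x drug MW / stock concentration;
    the mole count of polymer times the aim gives drug moles, converted to
    mass and then to stock volume.  Reported to 2 decimals.
    """
    if polymer_mg <= 0 or polymer_mn <= 0 or drug_mw <= 0 or stock_mg_per_ml <= 0:
        raise DomainError("masses, Mn, MW and concentration must be positive")
    if aimed_per_polymer < 0:
        raise DomainError("aimed count must be non-negative")
    volume = (polymer_mg / polymer_mn) * aimed_per_polymer * drug_mw / stock_mg_per_ml
    return FormulationPlan(
        polymer_mg=polymer_mg,
        polymer_mn=polymer_mn,
        drug=drug,
        drug_mw=drug_mw,
        aimed_per_polymer=aimed_per_polymer,
        stock_mg_per_ml=stock_mg_per_ml,
        stock_volume_ml=round(volume, 2),
    )


def loading_from_sim(
    aimed: int,
    n_attached: int,
    polymer: str = "",
    drug: str = "",
) -> EncapsulationRecord:
    """Bridge a final-frame attachment count to an encapsulation record."""
    return EncapsulationRecord(
        polymer=polymer,
        drug=drug,
        aimed_per_polymer=aimed,
        encapsulated_per_polymer=n_attached,
        efficiency_percent=efficiency(aimed, n_attached),
    )
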