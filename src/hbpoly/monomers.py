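"""Monomer building blocks for star-hyperbranched polyether growth.

A monomer is a ring-opened epoxide residue written as a SMILES fragment with
dummy atoms (``*``) marking attachment points.  The convention is:

* for non-core monomers the **first** dummy in the template is the inbound
  bond to the parent (always on a carbon: the alkoxide of the parent attacks
  the terminal CH2 of the epoxide);
* every further dummy is an **open substitution site** (always on an oxygen:
  the alkoxide formed on ring opening, or an activated hydroxyl);
* the core has no inbound dummy — all its dummies are open sites.

Unused open sites are capped as hydroxyls when a topology is rendered to a
real molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .errors import DomainError, InfeasibleConstraints

ROLES = ("core", "hydrophobic_linear", "glycidol_linear", "glycidol_dendritic", "terminal")

#: Residue masses in g/mol (ring-opening adds no/loses no atoms, so the
#: residue mass equals the monomer molecular weight).
_TMP_MASS = 134.17        # 1,1,1-tris(hydroxymethyl)propane core, C6H14O3
_EPOXYBUTANE_MASS = 72.11   # C4H8O
_EPOXYHEXANE_MASS = 100.16  # C6H12O
_GLYCIDOL_MASS = 74.08      # C3H6O2


@dataclass(frozen=True)
class MonomerSpec:
    """A chemical fragment with a role, open valences and a residue mass."""

    name: str
    role: str
    template: str
    n_attachment_points: int
    mass: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DomainError(f"unknown monomer role {self.role!r}")
        if self.mass <= 0:
            raise DomainError(f"monomer {self.name}: mass must be positive")
        if self.role == "terminal" and self.n_attachment_points != 0:
            raise DomainError(f"terminal monomer {self.name} must have 0 open sites")
        if self.role not in ("terminal",) and self.n_attachment_points < 1:
            raise DomainError(f"non-terminal monomer {self.name} needs >= 1 open site")
        frag = Chem.MolFromSmiles(self.template, sanitize=False)
        if frag is None:
            raise DomainError(f"monomer {self.name}: template does not parse")
        n_dummies = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 0)
        expected = self.n_attachment_points + (0 if self.role == "core" else 1)
        if n_dummies != expected:
            raise DomainError(
                f"monomer {self.name}: template has {n_dummies} attachment dummies, "
                f"expected {expected}"
            )

    @property
    def is_terminal(self) -> bool:
        return self.role == "terminal"

    @property
    def is_glycidol(self) -> bool:
        return self.role in ("glycidol_linear", "glycidol_dendritic")


@dataclass(frozen=True)
class GrowthConstraints:
    """Constraints steering stochastic growth toward a target composition.

    ``total_monomers`` is set by the target molecular weight;
    ``quantity_per_monomer`` encodes the experimentally derived monomer
    distribution.  Terminal monomers are only eligible while the running
    ramification ratio and the placed non-terminal fraction both sit at or
    above their thresholds, which prevents early capping of the branches.
    """

    total_monomers: int
    quantity_per_monomer: dict[str, int] = field(default_factory=dict)
    ramification_threshold: float = 0.5
    nonterminal_threshold: float = 0.5
    n_arms: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ramification_threshold <= 1.0:
            raise DomainError("ramification_threshold must lie in [0, 1]")
        if not 0.0 <= self.nonterminal_threshold <= 1.0:
            raise DomainError("nonterminal_threshold must lie in [0, 1]")
        if self.n_arms < 1:
            raise DomainError("n_arms must be >= 1")
        if any(q < 0 for q in self.quantity_per_monomer.values()):
            raise DomainError("monomer quantities must be non-negative")
        if sum(self.quantity_per_monomer.values()) != self.total_monomers:
            raise InfeasibleConstraints(
                "sum of quantity_per_monomer must equal total_monomers"
            )


def tmp_core(n_arms: int = 3) -> MonomerSpec:
    """1,1,1-tris(hydroxymethyl)propane core with ``n_arms`` activated arms."""
    if not 1 <= n_arms <= 3:
        raise DomainError("TMP core exposes between 1 and 3 arms")
    arms = ["CO*" if i < n_arms else "CO" for i in range(3)]
    template = f"CCC({arms[0]})({arms[1]}){arms[2]}"
    return MonomerSpec("TMP", "core", template, n_arms, _TMP_MASS)


def epoxybutane_unit() -> MonomerSpec:
    """Ring-opened 1,2-epoxybutane residue (ethyl side chain; R14 core block)."""
    return MonomerSpec("epoxybutane", "hydrophobic_linear", "*CC(CC)O*", 1, _EPOXYBUTANE_MASS)


def epoxyhexane_unit() -> MonomerSpec:
    """Ring-opened 1,2-epoxyhexane residue (butyl side chain; R17 core block)."""
    return MonomerSpec("epoxyhexane", "hydrophobic_linear", "*CC(CCCC)O*", 1, _EPOXYHEXANE_MASS)


def glycidol_dendritic_unit() -> MonomerSpec:
    """Glycidol residue with both oxygens available for further growth."""
    return MonomerSpec("glycidol_D", "glycidol_dendritic", "*CC(O*)CO*", 2, _GLYCIDOL_MASS)


def glycidol_linear_unit() -> MonomerSpec:
    """Glycidol residue propagating through its secondary alkoxide only."""
    return MonomerSpec("glycidol_L", "glycidol_linear", "*CC(O*)CO", 1, _GLYCIDOL_MASS)


def glycidol_terminal_unit() -> MonomerSpec:
    """Glycidol residue with both hydroxyls capped (chain end)."""
    return MonomerSpec("glycidol_T", "terminal", "*CC(O)CO", 0, _GLYCIDOL_MASS)


def r14_pool() -> tuple[list[MonomerSpec], GrowthConstraints]:
    """Pool and constraints for poly(1,2-epoxybutane)-co-HbPGL.

    Five epoxybutane units per arm on a three-arm TMP core (DPn = 3 x 5),
    with a glycidol shell sized so the formula molecular weight approximates
    the 15,700 g/mol measured for the purified copolymer.  Equal dendritic
    and linear glycidol counts keep the ramification ratio near 0.5 during
    growth, the regime the terminal-suppression rule is designed around.
    """
    pool = [
        tmp_core(3),
        epoxybutane_unit(),
        glycidol_dendritic_unit(),
        glycidol_linear_unit(),
        glycidol_terminal_unit(),
    ]
    quantities = {"epoxybutane": 15, "glycidol_D": 65, "glycidol_L": 65, "glycidol_T": 65}
    constraints = GrowthConstraints(
        total_monomers=sum(quantities.values()),
        quantity_per_monomer=quantities,
        n_arms=3,
    )
    return pool, constraints


def r17_pool() -> tuple[list[MonomerSpec], GrowthConstraints]:
    """Pool and constraints for poly(1,2-epoxyhexane)-co-HbPGL.

    Five epoxyhexane units per arm on a three-arm TMP core, glycidol shell
    sized to approximate the 8,500 g/mol measured for the purified copolymer.
    """
    pool = [
        tmp_core(3),
        epoxyhexane_unit(),
        glycidol_dendritic_unit(),
        glycidol_linear_unit(),
        glycidol_terminal_unit(),
    ]
    quantities = {"epoxyhexane": 15, "glycidol_D": 31, "glycidol_L": 31, "glycidol_T": 31}
    constraints = GrowthConstraints(
        total_monomers=sum(quantities.values()),
        quantity_per_monomer=quantities,
        n_arms=3,
    )
    return pool, constraints
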