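"""Deterministic toy fixtures: small pools, polymers, drugs and boxes.

Everything here is synthetic and desk-scale: a monomer pool small enough
for exhaustive enumeration of its legal topologies, a toy polymer of a few
dozen heavy atoms, a small nitroimidazole as a hydrogen-bonding model drug,
and a methanol box of a few thousand atoms.  All of it is generated from a
seed at call time; nothing is read from disk.
"""

from __future__ import annotations

from .chem import Molecule3D, embed_3d
from .grower import grow_polymer, topology_to_smiles
from .monomers import (
    GrowthConstraints,
    MonomerSpec,
    glycidol_dendritic_unit,
    glycidol_linear_unit,
    glycidol_terminal_unit,
    tmp_core,
)
from .system import SimulationSystem, build_solvated_system, place_drugs_around

__all__ = [
    "make_toy_pool",
    "make_toy_polymer",
    "make_toy_drug",
    "make_toy_encapsulation_system",
]

#: 2-methyl-5-nitro-1-(2-hydroxyethyl)imidazole: 12 heavy atoms, one
#: hydroxyl donor and several acceptors, a convenient model cargo.
TOY_DRUG_SMILES = "Cc1ncc([N+](=O)[O-])n1CCO"


def make_toy_pool(seed: int = 0) -> tuple[list[MonomerSpec], GrowthConstraints]:
    """A feasible three-arm pool whose legal topologies are enumerable.

    Six glycidol-type monomers (2 dendritic, 1 linear, 3 terminal) on a
    three-arm core: small enough for brute-force tree enumeration, rich
    enough to exercise the terminal-suppression constraints.
    """
    pool = [
        tmp_core(3),
        glycidol_dendritic_unit(),
        glycidol_linear_unit(),
        glycidol_terminal_unit(),
    ]
    quantities = {"glycidol_D": 2, "glycidol_L": 1, "glycidol_T": 3}
    constraints = GrowthConstraints(
        total_monomers=6,
        quantity_per_monomer=quantities,
        n_arms=3,
        seed=seed,
    )
    return pool, constraints


def make_toy_polymer(seed: int = 0) -> Molecule3D:
    """Toy polymer: grow the toy pool, render to SMILES, embed in 3D."""
    pool, constraints = make_toy_pool(seed)
    topo = grow_polymer(pool, constraints)
    mol = embed_3d(topology_to_smiles(topo), name="toy_polymer", seed=seed + 7)
    mol.residues = ["PLM"] * mol.n_atoms
    return mol


def make_toy_drug(seed: int = 0) -> Molecule3D:
    mol = embed_3d(TOY_DRUG_SMILES, name="toy_drug", seed=seed + 11)
    mol.residues = ["DRG"] * mol.n_atoms
    return mol


def make_toy_encapsulation_system(
    seed: int = 0,
    n_drugs: int = 6,
    margin: float = 2.0,
    nacl_molar: float = 0.15,
    max_atoms: int = 3000,
) -> SimulationSystem:
    """Toy polymer + six drug copies solvated in methanol, charge-neutral.

    The margin starts small and is shrunk deterministically when the random
    drug arrangement would push the solvated box past ``max_atoms``, so the
    fixture stays desk-scale for every seed.
    """
    polymer = make_toy_polymer(seed)
    drug = make_toy_drug(seed)
    drugs = place_drugs_around(polymer, drug, n=n_drugs, seed=seed + 13)
    system = None
    m = margin
    while True:
        system = build_solvated_system(
            [polymer, *drugs],
            solvent="methanol",
            margin=m,
            nacl_molar=nacl_molar,
            seed=seed + 17,
        )
        if system.n_atoms <= max_atoms or m <= 0.3:
            return system
        m = round(m - 0.25, 2)
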