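"""Solvent molecule templates and bulk number densities.

Water is a rigid 3-site molecule in either SPC or TIP3P geometry; methanol
and DMSO are all-atom templates embedded once from SMILES with a fixed seed
and cached.  Number densities (molecules per cubic Angstrom) come from the
room-temperature bulk densities and are used to pick lattice spacings when
filling boxes.
"""

from __future__ import annotations

import functools

import numpy as np

from .chem import Molecule3D, embed_3d
from .errors import DomainError

__all__ = ["solvent_template", "number_density", "SOLVENTS", "ion_template"]

#: identity -> (residue label, number density in molecules/A^3)
SOLVENTS = {
    "water-SPC": ("HOH", 0.0333),
    "water-TIP3P": ("HOH", 0.0333),
    "water": ("HOH", 0.0333),
    "methanol": ("MOH", 0.01487),
    "DMSO": ("DMS", 0.00848),
}

_WATER_GEOM = {
    # identity: (O-H bond length A, H-O-H angle deg)
    "water-SPC": (1.0, 109.47),
    "water": (1.0, 109.47),
    "water-TIP3P": (0.9572, 104.52),
}


def is_water(identity: str) -> bool:
    return identity.startswith("water")


def _rigid_water(bond: float, angle_deg: float, residue: str) -> Molecule3D:
    half = np.deg2rad(angle_deg) / 2
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [bond * np.sin(half), bond * np.cos(half), 0.0],
            [-bond * np.sin(half), bond * np.cos(half), 0.0],
        ]
    )
    return Molecule3D(
        "water", ["O", "H", "H"], coords, [(0, 1, 1), (0, 2, 1)],
        [0, 0, 0], [residue] * 3,
    )


@functools.lru_cache(maxsize=None)
def solvent_template(identity: str) -> Molecule3D:
    """Template molecule for a solvent identity, centered on its centroid."""
    if identity in _WATER_GEOM:
        bond, angle = _WATER_GEOM[identity]
        mol = _rigid_water(bond, angle, "HOH")
    elif identity == "methanol":
        mol = embed_3d("CO", "methanol")
        mol.residues = ["MOH"] * mol.n_atoms
    elif identity == "DMSO":
        mol = embed_3d("CS(C)=O", "DMSO")
        mol.residues = ["DMS"] * mol.n_atoms
    else:
        raise DomainError(f"unknown solvent identity {identity!r}")
    mol = mol.translated(-mol.coords.mean(axis=0))
    return mol


def number_density(identity: str) -> float:
    if identity not in SOLVENTS:
        raise DomainError(f"unknown solvent identity {identity!r}")
    return SOLVENTS[identity][1]


def residue_label(identity: str) -> str:
    if identity not in SOLVENTS:
        raise DomainError(f"unknown solvent identity {identity!r}")
    return SOLVENTS[identity][0]


def ion_template(kind: str, position) -> Molecule3D:
    """Single-atom monovalent ion (``'Na'`` or ``'Cl'``) at a position."""
    charges = {"Na": 1, "Cl": -1}
    labels = {"Na": "NA", "Cl": "CL"}
    if kind not in charges:
        raise DomainError(f"unknown ion kind {kind!r}")
    return Molecule3D(
        kind, [kind], np.asarray(position, float).reshape(1, 3), [],
        [charges[kind]], [labels[kind]],
    )
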