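"""Small-molecule utilities: SMILES to 3D, protonation rules, weights.

The 3D route follows the standard cheminformatics path: parse SMILES, add
explicit hydrogens, embed with distance geometry (ETKDG) and relax with a
short force-field minimization.  Protonation states are assigned from a small
pKa rule table rather than a predictor — the systems handled here (polyether
polymers, azole drugs) contain only a handful of ionizable group classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import EmbeddingFailure, ParseError, UnknownElement

__all__ = [
    "Molecule3D",
    "embed_3d",
    "protonate_for_pH",
    "molecular_weight",
    "polar_atom_selection",
    "ATOMIC_WEIGHTS",
]

#: IUPAC 2021 abridged standard atomic weights, g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ca": 40.078, "Br": 79.904, "I": 126.90,
}


@dataclass
class Molecule3D:
    """An all-atom molecule with coordinates in Angstrom."""

    name: str
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    formal_charges: list[int] = field(default_factory=list)
    residues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if self.coords.shape[0] != n:
            raise ValueError("coords/elements length mismatch")
        if not self.formal_charges:
            self.formal_charges = [0] * n
        if not self.residues:
            self.residues = ["MOL"] * n

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def net_charge(self) -> int:
        return int(sum(self.formal_charges))

    def copy(self) -> "Molecule3D":
        return Molecule3D(
            self.name,
            list(self.elements),
            self.coords.copy(),
            list(self.bonds),
            list(self.formal_charges),
            list(self.residues),
        )

    def translated(self, vec) -> "Molecule3D":
        out = self.copy()
        out.coords = out.coords + np.asarray(vec, float)
        return out

    def rotated(self, R: np.ndarray, about: np.ndarray | None = None) -> "Molecule3D":
        out = self.copy()
        pivot = out.coords.mean(axis=0) if about is None else np.asarray(about, float)
        out.coords = (out.coords - pivot) @ np.asarray(R, float).T + pivot
        return out

    def validate_geometry(self, min_dist: float = 0.5) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise EmbeddingFailure(f"{self.name}: non-finite coordinates")
        if self.n_atoms > 1:
            from scipy.spatial.distance import pdist

            if pdist(self.coords).min() < min_dist:
                raise EmbeddingFailure(f"{self.name}: atoms closer than {min_dist} A")

    # -- RDKit bridge -----------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "Molecule3D":
        mol = Chem.Mol(mol)
        # kekulize so aromatic bonds carry integer orders; aromaticity is
        # re-perceived on the way back in to_rdkit()
        Chem.Kekulize(mol, clearAromaticFlags=True)
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        return cls(
            name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else "MOL"),
            elements=[a.GetSymbol() for a in mol.GetAtoms()],
            coords=coords,
            bonds=[
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
                for b in mol.GetBonds()
            ],
            formal_charges=[a.GetFormalCharge() for a in mol.GetAtoms()],
        )

    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for el, q in zip(self.elements, self.formal_charges):
            a = Chem.Atom(el)
            a.SetFormalCharge(int(q))
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for i, j, o in self.bonds:
            rw.AddBond(int(i), int(j), orders.get(int(o), Chem.BondType.SINGLE))
        mol = rw.GetMol()
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        mol.AddConformer(conf)
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
        return mol


def embed_3d(smiles: str, name: str = "", seed: int = 20231028) -> Molecule3D:
    """Embed a SMILES string as an explicit-hydrogen 3D structure.

    Distance-geometry embedding (ETKDGv3, fixed seed for determinism)
    followed by MMFF94 relaxation (UFF fallback for elements MMFF lacks).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"SMILES does not parse: {smiles[:80]!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.useRandomCoords = mol.GetNumAtoms() > 800
    for attempt in range(3):
        params.randomSeed = seed + attempt
        if AllChem.EmbedMolecule(mol, params) == 0:
            break
    else:
        raise EmbeddingFailure(
            f"embedding failed for {mol.GetNumAtoms()} atoms after 3 attempts"
        )
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    except Exception:  # relaxation is best-effort; embedding already succeeded
        pass
    out = Molecule3D.from_rdkit(mol, name=name or "MOL")
    out.validate_geometry()
    return out


# pKa rule table: (SMARTS for the protonated/neutral form, pKa, action above pKa)
_PKA_RULES = [
    # carboxylic acid: deprotonate when pH > pKa
    ("[CX3](=O)[OX2H1]", 4.5, "deprotonate_oxygen"),
    # aliphatic amine (free lone pair): protonated below pKa ~ 10.5
    ("[NX3;H2,H1,H0;!$(N-C=O);!$(N-a);!$(N=*);!$([N+])]", 10.5, "protonate_nitrogen"),
    # imidazole / azole ring nitrogen: pKa ~ 6-7, neutral at physiological pH
    ("[nX2;$(n1ccnc1),$(n1ccn(c1))]", 6.0, "protonate_nitrogen"),
    # phenol: pKa ~ 10, neutral at physiological pH
    ("[c][OX2H1]", 10.0, "deprotonate_oxygen"),
]


def protonate_for_pH(mol: Molecule3D, pH: float = 7.4) -> Molecule3D:
    """Set protonation states of recognized ionizable groups at the given pH.

    Rule-table treatment: a group is (de)protonated when the pH is on the
    corresponding side of its class pKa.  Hydroxyls and ring nitrogens of
    azoles stay neutral at pH 7.4.  Groups outside the rule table are left
    neutral.  Idempotent at fixed pH.
    """
    rd = mol.to_rdkit()
    remove_h: list[tuple[int, int]] = []  # (oxygen idx, hydrogen idx)
    add_h: list[int] = []  # nitrogen idx
    handled: set[int] = set()

    for smarts, pka, action in _PKA_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in rd.GetSubstructMatches(patt):
            if action == "deprotonate_oxygen":
                o_idx = next(
                    (
                        i
                        for i in match
                        if rd.GetAtomWithIdx(i).GetSymbol() == "O"
                        and any(
                            n.GetSymbol() == "H"
                            for n in rd.GetAtomWithIdx(i).GetNeighbors()
                        )
                    ),
                    None,
                )
                if o_idx is None or o_idx in handled:
                    continue
                handled.add(o_idx)
                if pH > pka and mol.formal_charges[o_idx] == 0:
                    h_idx = next(
                        n.GetIdx()
                        for n in rd.GetAtomWithIdx(o_idx).GetNeighbors()
                        if n.GetSymbol() == "H"
                    )
                    remove_h.append((o_idx, h_idx))
            elif action == "protonate_nitrogen":
                n_idx = match[0]
                if n_idx in handled:
                    continue
                handled.add(n_idx)
                if pH < pka and mol.formal_charges[n_idx] == 0:
                    add_h.append(n_idx)

    out = mol.copy()
    for o_idx, _h in remove_h:
        out.formal_charges[o_idx] = -1
    removed = sorted(h for _o, h in remove_h)
    if removed:
        keep = [i for i in range(out.n_atoms) if i not in set(removed)]
        remap = {old: new for new, old in enumerate(keep)}
        out = Molecule3D(
            out.name,
            [out.elements[i] for i in keep],
            out.coords[keep],
            [
                (remap[i], remap[j], o)
                for i, j, o in out.bonds
                if i in remap and j in remap
            ],
            [out.formal_charges[i] for i in keep],
            [out.residues[i] for i in keep],
        )
        add_h = [remap[i] for i in add_h]
    for n_idx in add_h:
        out = _add_proton(out, n_idx)
        out.formal_charges[n_idx] = 1
    return out


def _add_proton(mol: Molecule3D, heavy_idx: int) -> Molecule3D:
    out = mol.copy()
    nbrs = [j for i, j, _ in mol.bonds if i == heavy_idx] + [
        i for i, j, _ in mol.bonds if j == heavy_idx
    ]
    center = mol.coords[heavy_idx]
    if nbrs:
        away = center - mol.coords[nbrs].mean(axis=0)
        norm = np.linalg.norm(away)
        direction = away / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
    else:
        direction = np.array([0.0, 0.0, 1.0])
    out.elements.append("H")
    out.coords = np.vstack([out.coords, center + 1.02 * direction])
    out.bonds.append((heavy_idx, out.n_atoms - 1, 1))
    out.formal_charges.append(0)
    out.residues.append(out.residues[heavy_idx])
    return out


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def molecular_weight(mol) -> float:
    """Molecular weight in g/mol from a molecule or a Hill formula string.

    Sums IUPAC standard atomic weights; reported to 2 decimals.
    """
    if isinstance(mol, str):
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(mol):
            if m.start() != pos:
                raise UnknownElement(f"cannot parse formula {mol!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(mol):
            raise UnknownElement(f"cannot parse formula {mol!r}")
        elements = [el for el, n in counts.items() for _ in range(n)]
    elif isinstance(mol, Molecule3D):
        elements = mol.elements
    elif isinstance(mol, Chem.Mol):
        with_h = Chem.AddHs(mol)
        elements = [a.GetSymbol() for a in with_h.GetAtoms()]
    else:
        raise TypeError("expected formula string, Molecule3D or RDKit Mol")
    total = 0.0
    for el in elements:
        if el not in ATOMIC_WEIGHTS:
            raise UnknownElement(f"no atomic weight for element {el!r}")
        total += ATOMIC_WEIGHTS[el]
    return round(total, 2)


def polar_atom_selection(mol: Molecule3D) -> set[int]:
    """Indices of polar atoms: N, O, S plus hydrogens bonded to N or O.

    Requires explicit hydrogens; used to restrict surface-area calculations
    to the polar surface.
    """
    polar = {i for i, el in enumerate(mol.elements) if el in ("N", "O", "S")}
    for i, j, _ in mol.bonds:
        ei, ej = mol.elements[i], mol.elements[j]
        if ei == "H" and ej in ("N", "O"):
            polar.add(i)
        elif ej == "H" and ei in ("N", "O"):
            polar.add(j)
    return polar


#: Reference drug structures (PubChem connectivity, written as SMILES).
DRUG_SMILES = {
    "tinidazole": "CCS(=O)(=O)CCn1c(C)ncc1[N+](=O)[O-]",
    "clotrimazole": "Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1",
}
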