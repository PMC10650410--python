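"""Solvated polymer-drug systems and the staged solvent-removal operations.

A :class:`SimulationSystem` holds solutes (polymer, drugs), intact solvent
molecules, monoatomic ions and an orthorhombic periodic box.  Boxes are built
with a configurable margin around the solutes (default 15 A per side) and
filled with solvent on a density-matched lattice with clash rejection; NaCl
is added at a target molarity plus counter-ions for neutrality.

Drying removes every solvent molecule whose minimum atom-to-atom distance to
any solute atom exceeds the shell radius, under the minimum-image convention.
Ions evaporate with the solvent except for the minimal counter-ion set needed
to keep the system neutral, which is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chem import Molecule3D
from .errors import BoxTooSmall, DomainError, OverlappingSolutes, PlacementFailure
from .solvent import (
    is_water,
    number_density,
    solvent_template,
    ion_template,
)

__all__ = [
    "SimulationSystem",
    "build_solvated_system",
    "place_drugs_around",
    "apply_drying_stage",
    "resolvate",
]

#: minimum solvent-to-solute atom distance when filling a box, A
CLASH_DISTANCE = 2.4
#: molarity -> ion pairs per A^3 (Avogadro scaling: mol/L x 6.022e-4)
MOLAR_TO_PER_A3 = 6.022e-4


@dataclass
class SimulationSystem:
    """Solutes + solvent + ions in an orthorhombic periodic box."""

    solutes: list[Molecule3D]
    solvent: list[Molecule3D]
    ions: list[Molecule3D]
    box: np.ndarray
    solvent_identity: dict[str, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return sum(m.n_atoms for m in self.all_molecules())

    def all_molecules(self) -> list[Molecule3D]:
        return [*self.solutes, *self.solvent, *self.ions]

    @property
    def net_charge(self) -> int:
        return sum(m.net_charge for m in self.solutes) + sum(
            m.net_charge for m in self.ions
        )

    def solvent_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.solvent:
            label = m.residues[0]
            counts[label] = counts.get(label, 0) + 1
        return counts

    def coords(self) -> np.ndarray:
        mols = self.all_molecules()
        if not mols:
            return np.zeros((0, 3))
        return np.concatenate([m.coords for m in mols])

    def elements(self) -> list[str]:
        out: list[str] = []
        for m in self.all_molecules():
            out.extend(m.elements)
        return out

    def with_coords(self, coords: np.ndarray) -> "SimulationSystem":
        """Same composition with replaced coordinates (atom order preserved)."""
        coords = np.asarray(coords, float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        out = SimulationSystem(
            [m.copy() for m in self.solutes],
            [m.copy() for m in self.solvent],
            [m.copy() for m in self.ions],
            self.box.copy(),
            dict(self.solvent_identity),
            dict(self.meta),
        )
        pos = 0
        for m in out.all_molecules():
            m.coords = coords[pos : pos + m.n_atoms].copy()
            pos += m.n_atoms
        return out

    def validate(self) -> None:
        """Type invariants: neutrality, intact solvent, atoms in box."""
        if self.net_charge != 0:
            raise ValueError(f"system not neutral: net charge {self.net_charge}")
        for m in self.solvent:
            if m.n_atoms < 1:
                raise ValueError("empty solvent molecule")
        wrapped = self.coords() % self.box
        if not np.all((wrapped >= 0) & (wrapped <= self.box)):
            raise ValueError("atoms outside box after wrapping")

    def wrapped_coords(self, coords: np.ndarray | None = None) -> np.ndarray:
        c = self.coords() if coords is None else coords
        return np.mod(c, self.box)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _solute_extent(solutes: list[Molecule3D]) -> tuple[np.ndarray, np.ndarray]:
    all_coords = np.concatenate([m.coords for m in solutes])
    return all_coords.min(axis=0), all_coords.max(axis=0)


def build_solvated_system(
    solutes: list[Molecule3D],
    solvent: str = "water-SPC",
    margin: float = 15.0,
    nacl_molar: float = 0.15,
    seed: int = 0,
) -> SimulationSystem:
    """Fully solvate solutes in a box with ``margin`` A on every side.

    The box edge along each axis is the solute extent plus twice the margin.
    Solvent molecules are placed on a cubic lattice at the solvent's bulk
    number density, randomly oriented, and rejected when any atom falls
    within 2.4 A of a solute atom.  NaCl pairs are added at ``nacl_molar``
    (pairs = round(molarity x 6.022e-4 x box volume)), plus counter-ions to
    neutralize any solute charge, by converting randomly chosen solvent
    molecules into ions.
    """
    if not solutes:
        raise DomainError("need at least one solute")
    if margin <= 0:
        raise BoxTooSmall("margin must be positive")
    _check_no_overlap(solutes)
    rng = np.random.default_rng(seed)

    lo, hi = _solute_extent(solutes)
    box = (hi - lo) + 2 * margin
    shift = margin - lo
    solutes = [m.translated(shift) for m in solutes]

    template = solvent_template(solvent)
    spacing = number_density(solvent) ** (-1 / 3)
    counts = np.maximum(1, np.floor(box / spacing).astype(int))
    solute_tree = cKDTree(np.concatenate([m.coords for m in solutes]))

    solvent_mols: list[Molecule3D] = []
    for ix in range(counts[0]):
        for iy in range(counts[1]):
            for iz in range(counts[2]):
                center = (np.array([ix, iy, iz]) + 0.5) * box / counts
                pose = template.rotated(_random_rotation(rng)).translated(center)
                if solute_tree.query(pose.coords, k=1)[0].min() < CLASH_DISTANCE:
                    continue
                solvent_mols.append(pose)

    n_pairs = int(round(nacl_molar * MOLAR_TO_PER_A3 * float(np.prod(box))))
    solute_charge = sum(m.net_charge for m in solutes)
    n_na = n_pairs + max(0, -solute_charge)
    n_cl = n_pairs + max(0, solute_charge)
    ions: list[Molecule3D] = []
    if n_na + n_cl > 0:
        if n_na + n_cl > len(solvent_mols):
            raise BoxTooSmall("not enough solvent molecules to place ions")
        chosen = rng.choice(len(solvent_mols), size=n_na + n_cl, replace=False)
        for k, idx in enumerate(chosen):
            kind = "Na" if k < n_na else "Cl"
            ions.append(ion_template(kind, solvent_mols[idx].coords.mean(axis=0)))
        keep = set(range(len(solvent_mols))) - set(int(i) for i in chosen)
        solvent_mols = [solvent_mols[i] for i in sorted(keep)]

    system = SimulationSystem(
        solutes=solutes,
        solvent=solvent_mols,
        ions=ions,
        box=box,
        solvent_identity={solvent: len(solvent_mols)},
    )
    system.validate()
    return system


def _check_no_overlap(solutes: list[Molecule3D], min_dist: float = 1.2) -> None:
    for i in range(len(solutes)):
        tree = cKDTree(solutes[i].coords)
        for j in range(i + 1, len(solutes)):
            if tree.query(solutes[j].coords, k=1)[0].min() < min_dist:
                raise OverlappingSolutes(
                    f"solutes {i} and {j} overlap (min distance < {min_dist} A)"
                )


def place_drugs_around(
    polymer: Molecule3D,
    drug: Molecule3D,
    n: int = 6,
    seed: int = 0,
    min_separation: float = 3.0,
    max_tries: int = 500,
) -> list[Molecule3D]:
    """Pose ``n`` randomly oriented drug copies on a shell around the polymer.

    Each copy sits just outside the polymer's bounding sphere with its
    orientation drawn uniformly; a pose is rejected unless every atom is at
    least ``min_separation`` A from the polymer and all previous copies.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    center = polymer.coords.mean(axis=0)
    r_poly = float(np.linalg.norm(polymer.coords - center, axis=1).max())
    drug_centered = drug.translated(-drug.coords.mean(axis=0))
    r_drug = float(np.linalg.norm(drug_centered.coords, axis=1).max()) if drug.n_atoms > 1 else 0.0

    placed: list[Molecule3D] = []
    trees = [cKDTree(polymer.coords)]
    for _k in range(n):
        for attempt in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = r_poly + r_drug + min_separation + rng.uniform(0.0, 2.0)
            pose = drug_centered.rotated(_random_rotation(rng)).translated(
                center + radius * direction
            )
            if all(t.query(pose.coords, k=1)[0].min() >= min_separation for t in trees):
                placed.append(pose)
                trees.append(cKDTree(pose.coords))
                break
        else:
            raise PlacementFailure(
                f"could not place drug copy {_k + 1}/{n} in {max_tries} tries"
            )
    return placed


def _min_distance_to_solute(
    system: SimulationSystem, coords: np.ndarray
) -> np.ndarray:
    """Minimum-image distance from each coordinate to the nearest solute atom."""
    solute_coords = np.concatenate([m.coords for m in system.solutes])
    tree = cKDTree(np.mod(solute_coords, system.box), boxsize=system.box)
    d, _ = tree.query(np.mod(coords, system.box), k=1)
    return d


def apply_drying_stage(
    system: SimulationSystem, shell_radius: float
) -> SimulationSystem:
    """Retain solvent only within ``shell_radius`` A of any solute atom.

    A solvent molecule survives iff its minimum atom-to-atom, minimum-image
    distance to the solute is at most the shell radius.  Ions follow the same
    rule, except that the counter-ions needed for neutrality are re-added
    (nearest first).  Solutes and the box are unchanged; the number of
    removed molecules is reported in ``meta['removed_solvent']``.
    """
    if shell_radius <= 0:
        raise DomainError("shell_radius must be positive")

    kept_solvent: list[Molecule3D] = []
    for m in system.solvent:
        if _min_distance_to_solute(system, m.coords).min() <= shell_radius:
            kept_solvent.append(m.copy())

    kept_ions: list[Molecule3D] = []
    removed_ions: list[tuple[float, Molecule3D]] = []
    for ion in system.ions:
        d = float(_min_distance_to_solute(system, ion.coords).min())
        if d <= shell_radius:
            kept_ions.append(ion.copy())
        else:
            removed_ions.append((d, ion))
    # restore neutrality with the closest evaporated counter-ions
    solute_charge = sum(m.net_charge for m in system.solutes)
    imbalance = solute_charge + sum(i.net_charge for i in kept_ions)
    removed_ions.sort(key=lambda t: t[0])
    for d, ion in removed_ions:
        if imbalance == 0:
            break
        if ion.net_charge * imbalance < 0:
            kept_ions.append(ion.copy())
            imbalance += ion.net_charge

    out = SimulationSystem(
        solutes=[m.copy() for m in system.solutes],
        solvent=kept_solvent,
        ions=kept_ions,
        box=system.box.copy(),
        solvent_identity={
            k: v for k, v in system.solvent_identity.items()
        },
        meta=dict(system.meta),
    )
    counts = out.solvent_counts()
    out.solvent_identity = {
        ident: counts.get(label, 0)
        for ident, label in _identity_labels(system).items()
    }
    out.meta["removed_solvent"] = len(system.solvent) - len(kept_solvent)
    out.validate()
    return out


def _identity_labels(system: SimulationSystem) -> dict[str, str]:
    from .solvent import residue_label

    return {ident: residue_label(ident) for ident in system.solvent_identity}


def resolvate(
    system: SimulationSystem,
    solvent: str = "water-SPC",
    margin: float = 15.0,
    nacl_molar: float = 0.15,
    seed: int = 0,
) -> SimulationSystem:
    """Re-solvate a (dried) system with a new solvent, keeping the residual.

    The box is rebuilt around the solutes with the given margin; residual
    solvent of other identities and existing ions are carried over, and the
    new solvent fills the remaining space by the same lattice rules as
    :func:`build_solvated_system`.  Additional NaCl is only added to top up
    to the target pair count for the new box volume.
    """
    if not system.solutes:
        raise DomainError("system has no solutes")
    rng = np.random.default_rng(seed)

    lo, hi = _solute_extent(system.solutes)
    box = (hi - lo) + 2 * margin
    shift = margin - lo
    solutes = [m.translated(shift) for m in system.solutes]
    residual = [m.translated(shift) for m in system.solvent]
    ions = [m.translated(shift) for m in system.ions]

    template = solvent_template(solvent)
    spacing = number_density(solvent) ** (-1 / 3)
    counts = np.maximum(1, np.floor(box / spacing).astype(int))
    occupied = [m.coords for m in (*solutes, *residual, *ions)]
    tree = cKDTree(np.concatenate(occupied))

    new_solvent: list[Molecule3D] = []
    for ix in range(counts[0]):
        for iy in range(counts[1]):
            for iz in range(counts[2]):
                center = (np.array([ix, iy, iz]) + 0.5) * box / counts
                pose = template.rotated(_random_rotation(rng)).translated(center)
                if tree.query(pose.coords, k=1)[0].min() < CLASH_DISTANCE:
                    continue
                new_solvent.append(pose)

    n_pairs_target = int(round(nacl_molar * MOLAR_TO_PER_A3 * float(np.prod(box))))
    have_pairs = min(
        sum(1 for i in ions if i.net_charge > 0),
        sum(1 for i in ions if i.net_charge < 0),
    )
    n_new = max(0, n_pairs_target - have_pairs)
    if n_new > 0 and 2 * n_new <= len(new_solvent):
        chosen = rng.choice(len(new_solvent), size=2 * n_new, replace=False)
        for k, idx in enumerate(chosen):
            kind = "Na" if k < n_new else "Cl"
            ions.append(ion_template(kind, new_solvent[idx].coords.mean(axis=0)))
        keep = set(range(len(new_solvent))) - set(int(i) for i in chosen)
        new_solvent = [new_solvent[i] for i in sorted(keep)]

    identity = dict.fromkeys(system.solvent_identity, 0)
    for ident in list(identity):
        counts_now = sum(
            1 for m in residual if m.residues[0] == _identity_labels(system)[ident]
        )
        identity[ident] = counts_now
    identity[solvent] = identity.get(solvent, 0) + len(new_solvent)

    out = SimulationSystem(
        solutes=solutes,
        solvent=[*residual, *new_solvent],
        ions=ions,
        box=box,
        solvent_identity=identity,
        meta=dict(system.meta),
    )
    out.validate()
    return out
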