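"""Per-frame observables: radius of gyration, polar surface area,
polymer-drug hydrogen bonds, drug clustering and attachment counts.

These are the quantities used to interpret drying and redissolution
trajectories: RG tracks polymer compactness, polar-restricted SASA tracks
the hydrophilic surface, hydrogen-bond and contact counts report how drug
molecules bind the polymer, and single-linkage clustering reports how the
drug molecules organize around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chem import ATOMIC_WEIGHTS, Molecule3D, polar_atom_selection
from .errors import EmptySelection, MissingRadius

__all__ = [
    "radius_of_gyration",
    "polar_surface_area",
    "count_hbonds",
    "cluster_drugs",
    "attached_drugs",
    "AnalysisSeries",
    "series_summary",
    "analyze_stage_results",
    "unwrap_molecule",
]

#: Bondi-style van der Waals radii, A.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "S": 1.80, "Cl": 1.75, "Na": 2.27, "P": 1.80, "Br": 1.85, "I": 1.98,
    "K": 2.75, "Mg": 1.73, "Ca": 2.31,
}


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration, A.

    RG = sqrt( sum m_i |r_i - r_bar|^2 / sum m_i ) with r_bar the
    mass-weighted centroid.
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    masses = np.asarray(masses, float)
    if coords.shape[0] == 0:
        raise EmptySelection("radius of gyration needs at least one atom")
    if masses.shape[0] != coords.shape[0]:
        raise ValueError("masses/coords length mismatch")
    centroid = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    sq = ((coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def molecule_rg(mol: Molecule3D) -> float:
    masses = np.array([ATOMIC_WEIGHTS[el] for el in mol.elements])
    return radius_of_gyration(mol.coords, masses)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def polar_surface_area(
    mol: Molecule3D, probe: float = 1.4, n_points: int = 960
) -> float:
    """Solvent-accessible surface area of the polar atoms, A^2.

    Shrake-Rupley numerical sampling: each atom's solvent-accessible sphere
    (vdW radius + probe) is covered with ``n_points`` quasi-uniform points,
    a point counts as exposed when no other atom's accessible sphere covers
    it, and only atoms in the polar selection (N, O, S and hydrogens on
    N/O) contribute their exposed area to the total.
    """
    polar = polar_atom_selection(mol)
    if not polar:
        return 0.0
    for el in set(mol.elements):
        if el not in VDW_RADII:
            raise MissingRadius(f"no van der Waals radius for {el!r}")
    radii = np.array([VDW_RADII[el] + probe for el in mol.elements])
    coords = mol.coords
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)

    total = 0.0
    r_max = radii.max()
    for i in sorted(polar):
        pts = coords[i] + radii[i] * unit
        # neighbors whose accessible sphere could cover any sample point
        nbr = [
            j
            for j in tree.query_ball_point(coords[i], radii[i] + r_max)
            if j != i
        ]
        if nbr:
            d = np.linalg.norm(
                pts[:, None, :] - coords[nbr][None, :, :], axis=2
            )
            exposed = np.all(d >= radii[nbr][None, :], axis=1)
        else:
            exposed = np.ones(n_points, dtype=bool)
        total += exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return float(total)


def _donors_and_acceptors(mol: Molecule3D):
    """(donor heavy atom, hydrogen) pairs and acceptor indices (N and O)."""
    donors = []
    for i, j, _ in mol.bonds:
        ei, ej = mol.elements[i], mol.elements[j]
        if ei in ("N", "O") and ej == "H":
            donors.append((i, j))
        elif ej in ("N", "O") and ei == "H":
            donors.append((j, i))
    acceptors = [i for i, el in enumerate(mol.elements) if el in ("N", "O")]
    return donors, acceptors


def count_hbonds(
    set_a: list[Molecule3D],
    set_b: list[Molecule3D],
    dist_cutoff: float = 3.5,
    angle_cutoff_deg: float = 120.0,
) -> int:
    """Count hydrogen bonds between two molecule sets.

    Geometric criterion: donor and acceptor are N or O, donor-acceptor
    distance <= ``dist_cutoff`` A, and the D-H...A angle at the hydrogen is
    at least ``angle_cutoff_deg``.  Donors in either set pair with acceptors
    in the other; each (D, H, A) triple counts once.
    """
    if not set_a or not set_b:
        return 0

    def directed(donor_mols, acceptor_mols) -> int:
        count = 0
        acc_coords = []
        for m in acceptor_mols:
            _, acc = _donors_and_acceptors(m)
            acc_coords.extend(m.coords[a] for a in acc)
        if not acc_coords:
            return 0
        acc_coords = np.array(acc_coords)
        tree = cKDTree(acc_coords)
        for m in donor_mols:
            donors, _ = _donors_and_acceptors(m)
            for d_idx, h_idx in donors:
                d_pos, h_pos = m.coords[d_idx], m.coords[h_idx]
                for a_j in tree.query_ball_point(d_pos, dist_cutoff):
                    a_pos = acc_coords[a_j]
                    v1 = d_pos - h_pos
                    v2 = a_pos - h_pos
                    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                    if n1 < 1e-9 or n2 < 1e-9:
                        continue
                    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
                    if np.degrees(np.arccos(cosang)) >= angle_cutoff_deg:
                        count += 1
        return count

    return directed(set_a, set_b) + directed(set_b, set_a)


def cluster_drugs(
    drugs: list[Molecule3D], cutoff: float = 4.0
) -> list[frozenset[int]]:
    """Single-linkage partition of drug molecules by atomic contact.

    Two drugs are connected when any inter-molecular atom pair lies within
    ``cutoff`` A; the partition is the connected components, returned as
    frozensets of drug indices sorted by their smallest member.
    """
    if not drugs:
        raise EmptySelection("need at least one drug molecule")
    n = len(drugs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    trees = [cKDTree(m.coords) for m in drugs]
    for i in range(n):
        for j in range(i + 1, n):
            if trees[i].query(drugs[j].coords, k=1)[0].min() <= cutoff:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted((frozenset(c) for c in comps.values()), key=min)


def attached_drugs(
    polymer: Molecule3D, drugs: list[Molecule3D], cutoff: float = 4.0
) -> int:
    """Number of drug molecules in atomic contact with the polymer."""
    return len(attached_drug_indices(polymer, drugs, cutoff))


def attached_drug_indices(
    polymer: Molecule3D, drugs: list[Molecule3D], cutoff: float = 4.0
) -> set[int]:
    tree = cKDTree(polymer.coords)
    return {
        k
        for k, m in enumerate(drugs)
        if tree.query(m.coords, k=1)[0].min() <= cutoff
    }


def unwrap_molecule(mol: Molecule3D, box: np.ndarray) -> Molecule3D:
    """Make a molecule whole under the minimum-image convention.

    Walks the bond graph from atom 0 and moves each atom to the periodic
    image nearest its already-placed neighbor, which repairs molecules split
    across the box boundary.
    """
    box = np.asarray(box, float)
    out = mol.copy()
    adj: dict[int, list[int]] = {}
    for i, j, _ in mol.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    visited = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in adj.get(i, []):
            if j in visited:
                continue
            delta = out.coords[j] - out.coords[i]
            out.coords[j] -= np.round(delta / box) * box
            visited.add(j)
            stack.append(j)
    return out


@dataclass
class AnalysisSeries:
    """Per-frame observables for a polymer-drug trajectory."""

    table: pd.DataFrame  # frame, rg, psa, n_hbonds, n_clusters, n_attached
    clusters: list[list[frozenset[int]]] = field(default_factory=list)
    attached_sets: list[set[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"frame", "rg", "n_hbonds", "n_clusters", "n_attached"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.table["rg"] < 0).any():
            raise ValueError("negative RG")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def analyze_stage_results(
    results,
    contact_cutoff: float = 4.0,
    hbond_dist: float = 3.5,
    hbond_angle: float = 120.0,
    compute_psa: bool = True,
    psa_points: int = 960,
) -> AnalysisSeries:
    """Compute the observable series over the frames of executed stages.

    The first solute is taken as the polymer and the remaining solutes as
    drug molecules; solutes are unwrapped by minimum image before measuring.
    """
    rows = []
    clusters_per_frame: list[list[frozenset[int]]] = []
    attached_per_frame: list[set[int]] = []
    frame_no = 0
    for res in results:
        for frame in res.frames:
            snap = res.system.with_coords(frame)
            polymer = unwrap_molecule(snap.solutes[0], snap.box)
            drugs = [unwrap_molecule(m, snap.box) for m in snap.solutes[1:]]
            rg = molecule_rg(polymer)
            psa = polar_surface_area(polymer, n_points=psa_points) if compute_psa else np.nan
            nhb = count_hbonds([polymer], drugs, hbond_dist, hbond_angle)
            part = cluster_drugs(drugs, contact_cutoff) if drugs else []
            att = attached_drug_indices(polymer, drugs, contact_cutoff)
            rows.append(
                {
                    "frame": frame_no,
                    "stage": res.stage.stage_name,
                    "rg": rg,
                    "psa": psa,
                    "n_hbonds": nhb,
                    "n_clusters": len(part),
                    "n_attached": len(att),
                }
            )
            clusters_per_frame.append(part)
            attached_per_frame.append(att)
            frame_no += 1
    return AnalysisSeries(
        table=pd.DataFrame(rows),
        clusters=clusters_per_frame,
        attached_sets=attached_per_frame,
    )


def series_summary(series: AnalysisSeries, window: slice | None = None) -> dict:
    """Windowed mean and fluctuation of each observable, plus release events.

    A release event is the first frame at which a drug molecule that was
    attached on the previous frame loses polymer contact.
    """
    tab = series.table if window is None else series.table.iloc[window]
    if len(tab) == 0:
        raise EmptySelection("summary window contains no frames")
    out: dict = {}
    for col in ("rg", "psa", "n_hbonds", "n_attached", "n_clusters"):
        if col in tab and not tab[col].isna().all():
            out[col] = {
                "mean": float(tab[col].mean()),
                "sd": float(tab[col].std(ddof=0)),
            }
    releases: dict[int, int] = {}
    prev: set[int] | None = None
    for frame_idx, att in zip(series.table["frame"], series.attached_sets):
        if prev is not None:
            for drug in prev - att:
                releases.setdefault(drug, int(frame_idx))
        prev = att
    out["release_events"] = releases
    return out
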