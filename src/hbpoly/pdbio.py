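"""Plain-text structure I/O: PDB (ATOM/HETATM + CONECT) and XYZ series.

The writer emits one residue per molecule (solvent residues HOH/MOH/DMS,
ions NA/CL, solutes keep their own labels), occupancy 1.00 and B-factor
0.00, with the element symbol in columns 77-78.  CONECT records are written
for solute molecules only; solvent connectivity is implied by the residue
template.  The reader groups atoms back into molecules by residue.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .chem import Molecule3D

__all__ = ["write_pdb", "read_pdb", "write_xyz_frames", "read_xyz_frames"]


def _format_atom_name(element: str, index_in_res: int) -> str:
    name = f"{element}{index_in_res % 100}"
    return name[:4]


def write_pdb(
    path,
    molecules: list[Molecule3D],
    box: np.ndarray | None = None,
    connect_for: set[int] | None = None,
) -> None:
    """Write molecules to a PDB file; ``connect_for`` selects molecule
    indices that get CONECT records (default: all with explicit bonds)."""
    lines: list[str] = []
    if box is not None:
        a, b, c = (float(x) for x in box)
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1"
        )
    serial = 1
    conect: list[str] = []
    for mol_idx, mol in enumerate(molecules):
        res_name = (mol.residues[0] if mol.residues else "MOL")[:3].upper()
        res_seq = (mol_idx % 9999) + 1
        start_serial = serial
        for i in range(mol.n_atoms):
            x, y, z = mol.coords[i]
            el = mol.elements[i]
            name = _format_atom_name(el, i)
            pad_name = f" {name:<3s}" if len(el) == 1 else f"{name:<4s}"
            lines.append(
                f"HETATM{(serial - 1) % 99999 + 1:5d} {pad_name}"
                f"{res_name:>4s} A{res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {el:>2s}"
            )
            serial += 1
        want_conect = connect_for is None or mol_idx in connect_for
        if want_conect and serial - 1 <= 99999:
            for i, j, _ in mol.bonds:
                conect.append(f"CONECT{start_serial + i:5d}{start_serial + j:5d}")
    lines.extend(conect)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> tuple[list[Molecule3D], np.ndarray | None]:
    """Read a PDB file back into molecules grouped by residue."""
    box = None
    atoms: list[tuple[int, str, str, int, np.ndarray]] = []
    conect: dict[int, set[int]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("CRYST1"):
            box = np.array(
                [float(line[6:15]), float(line[15:24]), float(line[24:33])]
            )
        elif line.startswith(("ATOM", "HETATM")):
            serial = int(line[6:11])
            res_name = line[17:20].strip()
            res_seq = int(line[22:26])
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            element = line[76:78].strip() or line[12:16].strip()[0]
            element = element.capitalize()
            atoms.append((serial, element, res_name, res_seq, xyz))
        elif line.startswith("CONECT"):
            fields = [line[i : i + 5] for i in range(6, len(line.rstrip()), 5)]
            serials = [int(f) for f in fields if f.strip()]
            if serials:
                conect.setdefault(serials[0], set()).update(serials[1:])

    groups: list[dict] = []
    current_key = None
    serial_to_local: dict[int, tuple[int, int]] = {}
    for serial, element, res_name, res_seq, xyz in atoms:
        key = (res_name, res_seq)
        if key != current_key:
            groups.append({"name": res_name, "elements": [], "coords": []})
            current_key = key
        g = groups[-1]
        serial_to_local[serial] = (len(groups) - 1, len(g["elements"]))
        g["elements"].append(element)
        g["coords"].append(xyz)
    molecules = [
        Molecule3D(
            g["name"],
            g["elements"],
            np.array(g["coords"]),
            [],
            [0] * len(g["elements"]),
            [g["name"]] * len(g["elements"]),
        )
        for g in groups
    ]
    seen_pairs: set[tuple[int, int]] = set()
    for src, dsts in conect.items():
        for dst in dsts:
            pair = (min(src, dst), max(src, dst))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            if src in serial_to_local and dst in serial_to_local:
                (mi, ai), (mj, aj) = serial_to_local[src], serial_to_local[dst]
                if mi == mj:
                    molecules[mi].bonds.append((ai, aj, 1))
    return molecules, box


def write_xyz_frames(path, elements: list[str], frames: list[np.ndarray]) -> None:
    """Write a multi-frame XYZ coordinate series."""
    lines: list[str] = []
    for k, frame in enumerate(frames):
        lines.append(str(len(elements)))
        lines.append(f"frame {k}")
        for el, (x, y, z) in zip(elements, frame):
            lines.append(f"{el:<2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_frames(path) -> tuple[list[str], list[np.ndarray]]:
    lines = Path(path).read_text().splitlines()
    pos = 0
    elements: list[str] = []
    frames: list[np.ndarray] = []
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        block = lines[pos + 2 : pos + 2 + n]
        frame = np.empty((n, 3))
        els = []
        for i, row in enumerate(block):
            parts = row.split()
            els.append(parts[0])
            frame[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if not elements:
            elements = els
        frames.append(frame)
        pos += 2 + n
    return elements, frames
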