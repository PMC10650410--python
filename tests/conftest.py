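"""Shared fixtures: tiny pools, hand-built molecules, enumeration oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hbpoly.chem import Molecule3D
from hbpoly.monomers import (
    GrowthConstraints,
    MonomerSpec,
    glycidol_dendritic_unit,
    glycidol_linear_unit,
    glycidol_terminal_unit,
    tmp_core,
)


@pytest.fixture
def toy_pool():
    from hbpoly.fixtures import make_toy_pool

    return make_toy_pool(seed=0)


@pytest.fixture
def tiny_pool():
    """core + 2 linear + 2 terminal: exhaustively enumerable."""
    from hbpoly.monomers import epoxybutane_unit

    pool = [tmp_core(2), epoxybutane_unit(), glycidol_terminal_unit()]
    constraints = GrowthConstraints(
        total_monomers=4,
        quantity_per_monomer={"epoxybutane": 2, "glycidol_T": 2},
        n_arms=2,
        seed=0,
    )
    return pool, constraints


def make_water(origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0), name="w"):
    """Water with one O-H along ``direction`` (for H-bond geometry tests)."""
    origin = np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0], 0.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.array([1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    h2 = origin + 0.96 * (np.cos(np.deg2rad(104.5)) * d + np.sin(np.deg2rad(104.5)) * perp)
    coords = np.array([origin, origin + 0.96 * d, h2])
    return Molecule3D(name, ["O", "H", "H"], coords, [(0, 1, 1), (0, 2, 1)])


def min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Brute-force minimum-image pairwise distances between coordinate sets."""
    delta = a[:, None, :] - b[None, :, :]
    delta -= np.round(delta / box) * box
    return np.linalg.norm(delta, axis=2)


# ---------------------------------------------------------------------------
# Exhaustive enumeration of legal topologies (the independent oracle)
# ---------------------------------------------------------------------------

def enumerate_legal_signatures(pool, constraints):
    """All canonical signatures of valence-legal full-consumption trees.

    Independent of the grower: recursive partition of the monomer multiset
    over child subtrees, deduplicated by generating child signatures in
    non-decreasing order.  Only valence and quantity conservation are
    enforced (growth-order constraints may reach a subset of these).
    """
    pool_map = {m.name: m for m in pool}
    names = sorted(constraints.quantity_per_monomer)
    full = tuple(constraints.quantity_per_monomer[n] for n in names)
    core = next(m for m in pool if m.role == "core")
    n_slots_root = min(core.n_attachment_points, constraints.n_arms)

    from functools import lru_cache

    def sub_compositions(comp):
        return itertools.product(*(range(c + 1) for c in comp))

    @lru_cache(maxsize=None)
    def subtree_sigs(root_name, comp):
        """Signatures of subtrees rooted at one ``root_name`` instance whose
        descendants consume exactly ``comp``."""
        spec = pool_map[root_name]
        results = set()

        def rec(remaining, slots, children, floor_sig):
            if sum(remaining) == 0:
                results.add((root_name, tuple(sorted(children))))
                return
            if slots == 0:
                return
            for i, n in enumerate(names):
                if remaining[i] == 0:
                    continue
                after_root = list(remaining)
                after_root[i] -= 1
                for sub in sub_compositions(tuple(after_root)):
                    if any(s > a for s, a in zip(sub, after_root)):
                        continue
                    for sig in subtree_sigs(n, sub):
                        if floor_sig is not None and sig < floor_sig:
                            continue
                        left = tuple(
                            a - s for a, s in zip(after_root, sub)
                        )
                        rec(left, slots - 1, children + (sig,), sig)

        rec(comp, spec.n_attachment_points, (), None)
        return frozenset(results)

    signatures = set()

    def rec_root(remaining, slots, children, floor_sig):
        if sum(remaining) == 0:
            signatures.add((core.name, tuple(sorted(children))))
            return
        if slots == 0:
            return
        for i, n in enumerate(names):
            if remaining[i] == 0:
                continue
            after_root = list(remaining)
            after_root[i] -= 1
            for sub in sub_compositions(tuple(after_root)):
                if any(s > a for s, a in zip(sub, after_root)):
                    continue
                for sig in subtree_sigs(n, sub):
                    if floor_sig is not None and sig < floor_sig:
                        continue
                    left = tuple(a - s for a, s in zip(after_root, sub))
                    rec_root(left, slots - 1, children + (sig,), sig)

    rec_root(full, n_slots_root, (), None)
    return signatures
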