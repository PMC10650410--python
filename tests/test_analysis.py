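"""Per-frame observables against brute-force and analytic oracles."""

import numpy as np
import pytest

from hbpoly.analysis import (
    VDW_RADII,
    attached_drugs,
    cluster_drugs,
    count_hbonds,
    molecule_rg,
    polar_surface_area,
    radius_of_gyration,
    series_summary,
    unwrap_molecule,
    AnalysisSeries,
)
from hbpoly.chem import Molecule3D, embed_3d
from hbpoly.errors import EmptySelection
from hbpoly.fixtures import make_toy_drug

from conftest import make_water


def _rand_rotation(rng):
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


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(50, 3)) * 5
        masses = rng.uniform(1, 16, size=50)
        # independent direct-sum evaluation
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        direct = np.sqrt(
            sum(m * np.dot(r - com, r - com) for m, r in zip(masses, coords))
            / masses.sum()
        )
        assert radius_of_gyration(coords, masses) == pytest.approx(direct, abs=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(30, 3))
        masses = rng.uniform(1, 32, size=30)
        base = radius_of_gyration(coords, masses)
        for _ in range(5):
            moved = coords @ _rand_rotation(rng).T + rng.normal(size=3) * 50
            assert radius_of_gyration(moved, masses) == pytest.approx(base, abs=1e-9)

    def test_empty_selection(self):
        with pytest.raises(EmptySelection):
            radius_of_gyration(np.zeros((0, 3)), np.zeros(0))


class TestPolarSurfaceArea:
    def test_methane_zero(self):
        assert polar_surface_area(embed_3d("C")) == 0.0

    def test_far_apart_atoms_match_analytic_spheres(self):
        # two "water oxygens" with no bonds, far apart: full spheres
        mol = Molecule3D(
            "oo",
            ["O", "O"],
            np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]),
        )
        r = VDW_RADII["O"] + 1.4
        analytic = 2 * 4 * np.pi * r**2
        assert polar_surface_area(mol, n_points=2000) == pytest.approx(
            analytic, rel=0.01
        )

    def test_isolated_water_near_full_sasa(self):
        w = embed_3d("O")
        psa = polar_surface_area(w)
        # all three atoms are polar; occlusion only from mutual overlap
        r_o = VDW_RADII["O"] + 1.4
        r_h = VDW_RADII["H"] + 1.4
        upper = 4 * np.pi * (r_o**2 + 2 * r_h**2)
        # at least the oxygen sphere (minus the two H caps) must be exposed
        assert 4 * np.pi * r_o**2 * 0.8 < psa < upper

    def test_convergence_with_sample_density(self):
        drug = make_toy_drug(0)
        coarse = polar_surface_area(drug, n_points=960)
        fine = polar_surface_area(drug, n_points=1920)
        assert abs(fine - coarse) / fine < 0.01


class TestCountHbonds:
    def test_linear_water_dimer(self):
        donor = make_water(origin=(0, 0, 0), direction=(1, 0, 0))
        acceptor = make_water(origin=(2.8, 0, 0), direction=(1, 0, 0))
        assert count_hbonds([donor], [acceptor]) >= 1

    def test_distant_molecules_zero(self):
        a = make_water(origin=(0, 0, 0))
        b = make_water(origin=(20, 0, 0))
        assert count_hbonds([a], [b]) == 0

    def test_empty_set_zero(self):
        assert count_hbonds([], [make_water()]) == 0
        assert count_hbonds([make_water()], []) == 0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        template = make_toy_drug(0)

        def random_pose(center):
            return template.rotated(_rand_rotation(rng)).translated(center)

        set_a = [random_pose(rng.uniform(0, 15, 3)) for _ in range(4)]
        set_b = [random_pose(rng.uniform(0, 15, 3)) for _ in range(4)]

        def oracle(mols_a, mols_b):
            """Independent O(N^3) triple loop over donor-H/acceptor triples."""
            total = 0
            for donors, acceptors in ((mols_a, mols_b), (mols_b, mols_a)):
                for md in donors:
                    dh = []
                    for i, j, _ in md.bonds:
                        if md.elements[i] in ("N", "O") and md.elements[j] == "H":
                            dh.append((i, j))
                        elif md.elements[j] in ("N", "O") and md.elements[i] == "H":
                            dh.append((j, i))
                    for ma in acceptors:
                        for d, h in dh:
                            for a, el in enumerate(ma.elements):
                                if el not in ("N", "O"):
                                    continue
                                if np.linalg.norm(md.coords[d] - ma.coords[a]) > 3.5:
                                    continue
                                v1 = md.coords[d] - md.coords[h]
                                v2 = ma.coords[a] - md.coords[h]
                                cosang = v1 @ v2 / (
                                    np.linalg.norm(v1) * np.linalg.norm(v2)
                                )
                                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 120:
                                    total += 1
            return total

        assert count_hbonds(set_a, set_b) == oracle(set_a, set_b)

    def test_symmetric_under_set_swap(self):
        rng = np.random.default_rng(9)
        template = make_toy_drug(0)
        a = [template.translated(rng.uniform(0, 8, 3)) for _ in range(3)]
        b = [template.translated(rng.uniform(0, 8, 3)) for _ in range(3)]
        assert count_hbonds(a, b) == count_hbonds(b, a)


class TestClusterDrugs:
    def _point_mol(self, xyz, name="p"):
        return Molecule3D(name, ["C"], np.asarray(xyz, float).reshape(1, 3))

    def test_all_far_apart_singletons(self):
        drugs = [self._point_mol([10 * i, 0, 0]) for i in range(5)]
        part = cluster_drugs(drugs, cutoff=4.0)
        assert len(part) == 5
        assert all(len(c) == 1 for c in part)

    def test_chain_transitivity(self):
        drugs = [
            self._point_mol([0, 0, 0]),
            self._point_mol([3, 0, 0]),
            self._point_mol([6, 0, 0]),
        ]
        part = cluster_drugs(drugs, cutoff=4.0)
        assert part == [frozenset({0, 1, 2})]

    def test_matches_connected_components_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        for _ in range(20):
            drugs = [self._point_mol(rng.uniform(0, 12, 3)) for _ in range(8)]
            part = cluster_drugs(drugs, cutoff=4.0)
            g = nx.Graph()
            g.add_nodes_from(range(len(drugs)))
            for i in range(len(drugs)):
                for j in range(i + 1, len(drugs)):
                    if np.linalg.norm(drugs[i].coords[0] - drugs[j].coords[0]) <= 4.0:
                        g.add_edge(i, j)
            oracle = sorted(
                (frozenset(c) for c in nx.connected_components(g)), key=min
            )
            assert part == oracle

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(8)
        drugs = [self._point_mol(rng.uniform(0, 10, 3)) for _ in range(6)]
        part = cluster_drugs(drugs, cutoff=4.0)
        perm = [3, 1, 5, 0, 4, 2]
        part_perm = cluster_drugs([drugs[i] for i in perm], cutoff=4.0)
        inv = {new: old for old, new in enumerate(perm)}
        remapped = sorted(
            (frozenset(perm[i] for i in c) for c in part_perm), key=min
        )
        assert remapped == part

    def test_partition_covers_all_drugs_once(self):
        rng = np.random.default_rng(2)
        drugs = [self._point_mol(rng.uniform(0, 10, 3)) for _ in range(7)]
        part = cluster_drugs(drugs, cutoff=4.0)
        members = sorted(i for c in part for i in c)
        assert members == list(range(7))


class TestAttachedDrugs:
    def _mol(self, xyz):
        coords = np.asarray(xyz, float).reshape(-1, 3)
        return Molecule3D("m", ["C"] * len(coords), coords)

    def test_all_far_zero(self):
        polymer = self._mol([[0, 0, 0], [1, 0, 0]])
        drugs = [self._mol([50, 50, 50]), self._mol([60, 0, 0])]
        assert attached_drugs(polymer, drugs) == 0

    def test_one_in_contact(self):
        polymer = self._mol([[0, 0, 0]])
        drugs = [self._mol([3, 0, 0]), self._mol([30, 0, 0])]
        assert attached_drugs(polymer, drugs, cutoff=4.0) == 1

    def test_matches_pair_scan_oracle_and_monotone_in_cutoff(self):
        rng = np.random.default_rng(6)
        polymer = Molecule3D("p", ["C"] * 40, rng.uniform(0, 10, (40, 3)))
        drugs = [
            Molecule3D("d", ["C"] * 5, rng.uniform(0, 25, (5, 3))) for _ in range(8)
        ]
        prev = -1
        for cutoff in (2.0, 4.0, 8.0, 16.0):
            got = attached_drugs(polymer, drugs, cutoff=cutoff)
            oracle = sum(
                1
                for d in drugs
                if np.min(
                    np.linalg.norm(
                        polymer.coords[:, None, :] - d.coords[None, :, :], axis=2
                    )
                )
                <= cutoff
            )
            assert got == oracle
            assert got >= prev
            prev = got
        assert prev <= len(drugs)


class TestUnwrap:
    def test_repairs_molecule_split_across_boundary(self):
        box = np.array([10.0, 10.0, 10.0])
        # diatomic wrapped: atom 0 near box max, atom 1 wrapped to near 0
        mol = Molecule3D(
            "d",
            ["C", "C"],
            np.array([[9.5, 5.0, 5.0], [0.5, 5.0, 5.0]]),
            [(0, 1, 1)],
        )
        fixed = unwrap_molecule(mol, box)
        assert np.linalg.norm(fixed.coords[1] - fixed.coords[0]) == pytest.approx(1.0)


class TestSeriesSummary:
    def _series(self, rows, attached_sets):
        import pandas as pd

        return AnalysisSeries(
            table=pd.DataFrame(rows),
            clusters=[[] for _ in rows],
            attached_sets=attached_sets,
        )

    def test_constant_series(self):
        rows = [
            {"frame": i, "rg": 5.0, "psa": 100.0, "n_hbonds": 2,
             "n_clusters": 1, "n_attached": 3}
            for i in range(4)
        ]
        s = self._series(rows, [{0, 1, 2}] * 4)
        out = series_summary(s)
        assert out["rg"]["mean"] == 5.0 and out["rg"]["sd"] == 0.0
        assert out["release_events"] == {}

    def test_alternating_hbond_counts(self):
        rows = [
            {"frame": i, "rg": 1.0, "psa": 1.0, "n_hbonds": v,
             "n_clusters": 1, "n_attached": 0}
            for i, v in enumerate([1, 3, 1, 3])
        ]
        s = self._series(rows, [set()] * 4)
        assert series_summary(s)["n_hbonds"]["mean"] == pytest.approx(2.0)

    def test_release_event_first_detachment_frame(self):
        rows = [
            {"frame": i, "rg": 1.0, "psa": 1.0, "n_hbonds": 0,
             "n_clusters": 1, "n_attached": n}
            for i, n in enumerate([2, 2, 1, 1, 0])
        ]
        attached = [{0, 1}, {0, 1}, {0}, {0}, set()]
        out = series_summary(self._series(rows, attached))
        assert out["release_events"] == {1: 2, 0: 4}

    def test_summary_equals_direct_recomputation_on_jitter_run(self):
        from hbpoly.engines import JitterEngine
        from hbpoly.fixtures import make_toy_encapsulation_system
        from hbpoly.schedule import schedule_from_preset, run_schedule
        from hbpoly.analysis import analyze_stage_results

        system = make_toy_encapsulation_system(seed=1)
        sched = schedule_from_preset("clotrimazole", duration_scale=0.05)
        results = run_schedule(
            system, sched, JitterEngine(), seed=2, resolvate_margin=3.0
        )
        series = analyze_stage_results(results, compute_psa=False)
        out = series_summary(series)
        tab = series.table
        assert out["rg"]["mean"] == pytest.approx(tab["rg"].mean())
        assert out["rg"]["sd"] == pytest.approx(tab["rg"].std(ddof=0))
        assert out["n_attached"]["mean"] == pytest.approx(tab["n_attached"].mean())
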