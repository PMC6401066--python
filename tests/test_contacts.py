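"""Contact occupancy against brute-force oracles, invariances, aggregation."""

import numpy as np
import pandas as pd
import pytest

from sas6flex import (
    Trajectory,
    aggregate_replicates,
    contact_occupancy,
    residue_min_distance,
)
from sas6flex.contacts import parse_selection
from sas6flex.synthetic import ToyDimerSpec, gen_loop_trajectory

from conftest import random_toy_trajectory


def brute_force_occupancy(traj, keys_a, keys_b, cutoff, atom_filter="heavy"):
    """Independent oracle: per-frame python double loop over atom pairs."""
    occ = {}
    for ka in keys_a:
        for kb in keys_b:
            hits = 0
            for f in range(traj.n_frames):
                dmin = np.inf
                for i in traj.atom_indices(ka, atom_filter):
                    for j in traj.atom_indices(kb, atom_filter):
                        d = np.linalg.norm(traj.coords[f, i] - traj.coords[f, j])
                        dmin = min(dmin, d)
                if dmin < cutoff:
                    hits += 1
            occ[(ka, kb)] = hits / traj.n_frames
    return occ


def two_residue_frame(pos_a, pos_b):
    atoms = pd.DataFrame(
        {
            "chain": ["A"] * len(pos_a) + ["B"] * len(pos_b),
            "resid": [1] * len(pos_a) + [1] * len(pos_b),
            "resname": "GLY",
            "name": [f"C{i}" for i in range(len(pos_a))] + [f"C{i}" for i in range(len(pos_b))],
            "element": "C",
        }
    )
    coords = np.asarray([pos_a + pos_b], dtype=float)
    return Trajectory(coords=coords, atoms=atoms)


class TestMinDistance:
    def test_single_atom_residues(self):
        traj = two_residue_frame([[0, 0, 0]], [[3, 0, 0]])
        assert residue_min_distance(traj, 0, ("A", 1), ("B", 1)) == pytest.approx(3.0)

    def test_min_semantics_over_atom_pairs(self):
        traj = two_residue_frame([[0, 0, 0], [9, 0, 0]], [[2, 0, 0], [9, 9, 0]])
        assert residue_min_distance(traj, 0, ("A", 1), ("B", 1)) == pytest.approx(2.0)

    def test_matches_double_loop_on_random_residues(self):
        traj = random_toy_trajectory(n_frames=3, n_residues_per_chain=4, atoms_per_residue=5, seed=9)
        for f in range(3):
            d = residue_min_distance(traj, f, ("A", 2), ("B", 3), atom_filter="all")
            ia = traj.atom_indices(("A", 2), "all")
            ib = traj.atom_indices(("B", 3), "all")
            oracle = min(
                np.linalg.norm(traj.coords[f, i] - traj.coords[f, j]) for i in ia for j in ib
            )
            assert d == pytest.approx(oracle, rel=1e-12)

    def test_heavy_filter_excludes_hydrogens(self):
        atoms = pd.DataFrame(
            {
                "chain": ["A", "A", "B"],
                "resid": [1, 1, 1],
                "resname": "GLY",
                "name": ["C1", "H1", "C1"],
                "element": ["C", "H", "C"],
            }
        )
        coords = np.array([[[0, 0, 0], [4.5, 0, 0], [5, 0, 0]]], dtype=float)
        traj = Trajectory(coords=coords, atoms=atoms)
        assert residue_min_distance(traj, 0, ("A", 1), ("B", 1), "heavy") == pytest.approx(5.0)
        assert residue_min_distance(traj, 0, ("A", 1), ("B", 1), "all") == pytest.approx(0.5)

    def test_missing_residue_errors(self):
        traj = two_residue_frame([[0, 0, 0]], [[1, 0, 0]])
        with pytest.raises(KeyError):
            residue_min_distance(traj, 0, ("A", 99), ("B", 1))


class TestOccupancy:
    def test_equals_brute_force_on_random_toy_system(self):
        traj = random_toy_trajectory(n_frames=20, n_residues_per_chain=15, seed=4)
        keys_a = parse_selection("A:1-15")
        keys_b = parse_selection("B:1-15")
        occ = contact_occupancy(traj, "A:1-15", "B:1-15", cutoff=5.0)
        oracle = brute_force_occupancy(traj, keys_a, keys_b, 5.0)
        for row in occ.pairs.itertuples():
            key = ((row.chain_a, row.resid_a), (row.chain_b, row.resid_b))
            assert row.occupancy == oracle[key]  # exact integer frame counts

    def test_strict_inequality_at_cutoff(self):
        traj = two_residue_frame([[0, 0, 0]], [[3.5, 0, 0]])
        occ = contact_occupancy(traj, [("A", 1)], [("B", 1)], cutoff=3.5)
        assert occ.pairs["occupancy"].iloc[0] == 0.0

    def test_planted_always_and_never_contacts(self):
        always = gen_loop_trajectory(ToyDimerSpec(p_on=1.0, p_stay=1.0, seed=2), 25)
        occ = contact_occupancy(always, "A:10-20", "B:2-8")
        # every loop residue touches its planted partner in every frame
        assert np.all(occ.marginal_a["occupancy_any"] == 1.0)
        never = gen_loop_trajectory(ToyDimerSpec(p_on=0.0, seed=2), 25)
        occ0 = contact_occupancy(never, "A:10-20", "B:2-8")
        assert np.all(occ0.pairs["occupancy"] == 0.0)

    def test_frame_permutation_invariance(self):
        traj = random_toy_trajectory(n_frames=12, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = Trajectory(coords=traj.coords[perm], atoms=traj.atoms)
        a, b = "A:1-6", "B:1-6"
        occ1 = contact_occupancy(traj, a, b, cutoff=5.0)
        occ2 = contact_occupancy(shuffled, a, b, cutoff=5.0)
        assert np.array_equal(occ1.pairs["occupancy"], occ2.pairs["occupancy"])

    def test_group_swap_symmetry(self):
        traj = random_toy_trajectory(n_frames=8, seed=6)
        occ_ab = contact_occupancy(traj, "A:1-5", "B:1-5", cutoff=5.0)
        occ_ba = contact_occupancy(traj, "B:1-5", "A:1-5", cutoff=5.0).transposed()
        merged = occ_ab.pairs.merge(
            occ_ba.pairs, on=["chain_a", "resid_a", "chain_b", "resid_b"], suffixes=("_1", "_2")
        )
        assert len(merged) == len(occ_ab.pairs)
        assert np.array_equal(merged["occupancy_1"], merged["occupancy_2"])

    def test_chunked_equals_whole(self):
        traj = random_toy_trajectory(n_frames=10, seed=7)
        half1 = Trajectory(coords=traj.coords[:4], atoms=traj.atoms)
        half2 = Trajectory(coords=traj.coords[4:], atoms=traj.atoms)
        a, b = "A:1-4", "B:1-4"
        whole = contact_occupancy(traj, a, b, cutoff=5.0).pairs["occupancy"]
        c1 = contact_occupancy(half1, a, b, cutoff=5.0).pairs["occupancy"]
        c2 = contact_occupancy(half2, a, b, cutoff=5.0).pairs["occupancy"]
        recombined = (c1 * 4 + c2 * 6) / 10
        assert np.allclose(whole, recombined, atol=1e-15)

    def test_monotone_in_cutoff(self):
        traj = random_toy_trajectory(n_frames=10, seed=8)
        occ_small = contact_occupancy(traj, "A:1-6", "B:1-6", cutoff=3.0).pairs["occupancy"]
        occ_large = contact_occupancy(traj, "A:1-6", "B:1-6", cutoff=6.0).pairs["occupancy"]
        assert np.all(occ_large >= occ_small)

    def test_overlapping_groups_rejected(self):
        traj = random_toy_trajectory(n_frames=2, seed=1)
        with pytest.raises(ValueError, match="disjoint"):
            contact_occupancy(traj, "A:1-5", "A:3-8", cutoff=5.0)


class TestAggregate:
    def test_single_run_identity(self):
        traj = gen_loop_trajectory(ToyDimerSpec(p_on=0.5, seed=3), 60)
        occ = contact_occupancy(traj, "A:10-20", "B:2-8")
        summary = aggregate_replicates([occ])
        assert np.array_equal(summary["mean"], occ.marginal_a["occupancy_any"])

    def test_mean_across_runs(self):
        runs = [
            contact_occupancy(
                gen_loop_trajectory(ToyDimerSpec(p_on=0.5, seed=s), 50), "A:10-20", "B:2-8"
            )
            for s in range(3)
        ]
        summary = aggregate_replicates(runs)
        stacked = np.column_stack([r.marginal_a["occupancy_any"] for r in runs])
        assert np.allclose(summary["mean"], stacked.mean(axis=1))

    def test_high_occupancy_loop_flagged_flanks_not(self):
        runs = [
            contact_occupancy(
                gen_loop_trajectory(ToyDimerSpec(p_on=0.7, p_stay=0.7, seed=s), 300),
                "A:10-25", "B:2-8",
            )
            for s in range(3)
        ]
        summary = aggregate_replicates(runs)
        loop = summary["resid"].between(10, 20)
        assert summary.loc[loop, "flagged"].all()
        assert not summary.loc[~loop, "flagged"].any()

    def test_mismatched_cutoffs_rejected(self):
        traj = gen_loop_trajectory(ToyDimerSpec(seed=0), 10)
        r1 = contact_occupancy(traj, "A:10-20", "B:2-8", cutoff=3.5)
        r2 = contact_occupancy(traj, "A:10-20", "B:2-8", cutoff=4.0)
        with pytest.raises(ValueError, match="cutoff"):
            aggregate_replicates([r1, r2])


def test_selection_parsing():
    assert parse_selection("A:3-5") == [("A", 3), ("A", 4), ("A", 5)]
    assert parse_selection([("B", 7)]) == [("B", 7)]
    with pytest.raises(ValueError):
        parse_selection("A:5-3")
    with pytest.raises(ValueError):
        parse_selection("nonsense")
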