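"""Nonbonded force kernel and punctual-stress reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forcemode as fm
from forcemode.forces import SingularGeometryError

from oracles import oracle_pair_force, oracle_punctual_stress

BOX = np.array([6.0, 6.0, 6.0])


class TestPairAtomForce:
    def test_coulomb_closed_form_at_1nm(self):
        # two unit charges 1 nm apart, no LJ: |F| = the electric
        # conversion factor itself, directed repulsively
        f = fm.pair_atom_force([0, 0, 0], [1.0, 0, 0], 1.0, 1.0,
                               0.3, 0.0, BOX)
        assert np.isclose(np.linalg.norm(f), fm.COULOMB_CONSTANT, rtol=1e-12)
        assert f[0] < 0  # force on a points away from b

    def test_zero_beyond_cutoff(self):
        f = fm.pair_atom_force([0, 0, 0], [1.3, 0, 0], 0.4, -0.3,
                               0.33, 0.6, BOX)
        assert np.all(f == 0.0)

    def test_lj_force_vanishes_at_potential_minimum(self):
        r = 2 ** (1 / 6) * 0.3  # < r_switch: plain LJ applies
        f = fm.pair_atom_force([0, 0, 0], [r, 0, 0], 0.0, 0.0, 0.3, 0.5, BOX)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_coincident_atoms_raise(self):
        with pytest.raises(SingularGeometryError):
            fm.pair_atom_force([1, 1, 1], [1, 1, 1], 0.1, 0.1, 0.3, 0.5, BOX)

    def test_minimum_image_is_applied(self):
        # 5.5 nm apart in a 6 nm box is really 0.5 nm through the wall
        f_wrapped = fm.pair_atom_force([0.25, 3, 3], [5.75, 3, 3],
                                       0.2, 0.2, 0.3, 0.5, BOX)
        f_direct = fm.pair_atom_force([0.25, 3, 3], [-0.25, 3, 3],
                                      0.2, 0.2, 0.3, 0.5, BOX)
        assert np.allclose(f_wrapped, f_direct, rtol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_newton_third_law(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(1.0, 5.0, 3)
        b = a + rng.uniform(-1.3, 1.3, 3)
        if np.linalg.norm(a - b) < 1e-3:
            b = a + 0.5
        q_a, q_b = rng.uniform(-0.5, 0.5, 2)
        sigma, eps = rng.uniform(0.25, 0.35), rng.uniform(0.2, 0.8)
        f_ab = fm.pair_atom_force(a, b, q_a, q_b, sigma, eps, BOX)
        f_ba = fm.pair_atom_force(b, a, q_b, q_a, sigma, eps, BOX)
        assert np.allclose(f_ab, -f_ba, atol=1e-12)

    def test_force_switch_continuity_at_cutoff(self):
        # LJ-only radial scan: |F| decays smoothly to zero at r_cut and
        # is continuous across r_switch
        radii = np.linspace(0.95, 1.25, 400)
        mags = [np.linalg.norm(fm.pair_atom_force([0, 0, 0], [r, 0, 0],
                                                  0.0, 0.0, 0.3, 0.5, BOX))
                for r in radii]
        mags = np.asarray(mags)
        inside = radii <= fm.R_CUT
        assert np.all(mags[~inside] == 0.0)
        # vanishing magnitude approaching the cutoff from below
        near = (radii > fm.R_CUT - 1e-3) & inside
        assert np.all(mags[near] < 1e-4)
        # no jumps anywhere on the scan (switch window is C1)
        assert np.max(np.abs(np.diff(mags))) < 0.5


class TestResidueLipidForce:
    def test_single_atom_pair_equals_pair_force(self, small_system):
        s = fm.generate_toy_system(2, 1, 1, seed=7)
        res = s.protein_residue_ids[0]
        lip = s.lipid_molecule_ids[0]
        pf = fm.residue_lipid_force(s, s.positions, res, lip)
        ia, ib = s.residue_atoms(res)[0], s.molecule_atoms(lip)[0]
        sigma = 0.5 * (s.lj_sigma[ia] + s.lj_sigma[ib])
        eps = np.sqrt(s.lj_epsilon[ia] * s.lj_epsilon[ib])
        expected = fm.pair_atom_force(s.positions[ia], s.positions[ib],
                                      s.charges[ia], s.charges[ib],
                                      sigma, eps, s.box)
        assert np.allclose(pf.force, expected, rtol=1e-12)

    def test_out_of_range_indices_raise(self, small_system):
        with pytest.raises(IndexError):
            fm.residue_lipid_force(small_system, small_system.positions,
                                   9999, small_system.lipid_molecule_ids[0])
        with pytest.raises(IndexError):
            fm.residue_lipid_force(small_system, small_system.positions,
                                   small_system.protein_residue_ids[0], 9999)

    def test_distant_lipid_gives_zero(self, small_system):
        s = small_system
        plan = s.metadata["lipid_inside_plan"]
        outside = [lip for lip, inside in zip(s.lipid_molecule_ids, plan)
                   if not inside]
        for lip in outside:
            for res in s.protein_residue_ids:
                f = fm.residue_lipid_force(s, s.positions, res, lip)
                assert np.all(f.force == 0.0)


class TestPunctualStress:
    def test_matches_bruteforce_on_random_systems(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            s = fm.generate_toy_system(int(rng.integers(2, 6)),
                                       int(rng.integers(1, 8)),
                                       int(rng.integers(1, 4)),
                                       seed=int(rng.integers(1_000_000)))
            got = fm.punctual_stress(s, s.positions)
            expected = oracle_punctual_stress(s, s.positions)
            assert np.allclose(got, expected, rtol=1e-10)

    def test_magnitudes_add_across_opposing_lipids(self):
        # one residue pulled equally in opposite directions by two
        # lipids: PS sums magnitudes, it does not cancel vectors
        pos = np.array([[3.0, 3.0, 3.0],
                        [3.8, 3.0, 3.0],
                        [2.2, 3.0, 3.0]])
        s = fm.ToySystem(
            positions=pos, charges=[0.3, 0.2, 0.2],
            lj_sigma=[0.3] * 3, lj_epsilon=[0.5] * 3,
            residue_index=[0, 1, 2], molecule_index=[0, 1, 2],
            group_tag=["protein", "lipid", "lipid"],
            chain_tag=["A", "none", "none"], box=BOX)
        per_lipid = [np.linalg.norm(
            fm.residue_lipid_force(s, pos, 0, j).force) for j in (1, 2)]
        assert per_lipid[0] > 0
        ps = fm.punctual_stress(s, pos)
        assert np.isclose(ps[0], sum(per_lipid), rtol=1e-12)

    def test_no_lipids_returns_zeros(self):
        s = fm.generate_toy_system(3, 1, 2, seed=5)
        keep = s.protein_mask
        pruned = fm.ToySystem(
            positions=s.positions[keep], charges=s.charges[keep],
            lj_sigma=s.lj_sigma[keep], lj_epsilon=s.lj_epsilon[keep],
            residue_index=s.residue_index[keep],
            molecule_index=s.molecule_index[keep],
            group_tag=s.group_tag[keep], chain_tag=s.chain_tag[:3],
            box=s.box)
        assert np.all(fm.punctual_stress(pruned, pruned.positions) == 0.0)

    def test_nonnegative(self, small_system):
        ps = fm.punctual_stress(small_system, small_system.positions)
        assert np.all(ps >= 0.0)

    def test_cutoff_locality(self):
        # moving a lipid that stays beyond the cutoff of every residue
        # leaves every PS value bit-identical
        s = fm.generate_toy_system(5, 6, 2, seed=3)
        plan = s.metadata["lipid_inside_plan"]
        outside_mol = [lip for lip, inside
                       in zip(s.lipid_molecule_ids, plan) if not inside][0]
        before = fm.punctual_stress(s, s.positions)
        moved = s.positions.copy()
        moved[s.molecule_atoms(outside_mol)] += np.array([0.0, 0.0, 0.05])
        after = fm.punctual_stress(s, moved)
        assert np.array_equal(before, after)


class TestStressTrajectory:
    def test_single_frame_matches_punctual_stress(self, small_system):
        series = fm.stress_trajectory(small_system, [small_system.positions])
        assert series.values.shape == (1, len(small_system.protein_residue_ids))
        assert np.array_equal(series.values[0],
                              fm.punctual_stress(small_system,
                                                 small_system.positions))

    def test_identical_frames_identical_rows_and_times(self, small_system):
        series = fm.stress_trajectory(small_system,
                                      [small_system.positions] * 4)
        assert np.all(series.values == series.values[0])
        assert np.array_equal(series.frame_times, [0.0, 40.0, 80.0, 120.0])

    def test_rows_match_per_frame_oracle(self):
        s = fm.generate_toy_system(3, 4, 2, seed=9)
        traj = fm.generate_transition_trajectory(s, 0.05, 4, seed=2,
                                                 jitter_sigma=0.01)
        series = fm.stress_trajectory(s, traj.frames)
        for row, frame in zip(series.values, traj.frames):
            assert np.allclose(row, oracle_punctual_stress(s, frame),
                               rtol=1e-10)

    def test_atom_count_mismatch_raises(self, small_system):
        with pytest.raises(ValueError):
            fm.stress_trajectory(small_system, [np.zeros((3, 3))])


def test_stress_profile_z_orders_bins_along_membrane_normal(small_system):
    ps = fm.punctual_stress(small_system, small_system.positions)
    centers, profile = fm.stress_profile_z(small_system, ps, n_bins=5)
    assert len(centers) == len(profile) == 5
    assert np.all(np.diff(centers) > 0)
    assert np.nansum(profile) > 0
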