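"""Trajectory metrics: H-bond geometry, distances, RMSD, RMSF."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from alchemti import (
    Atom,
    HBondSpec,
    InvalidInputError,
    Trajectory,
    distance_series,
    generate_fluct_traj,
    hbond_occupancy,
    hbond_present,
    read_pdb_trajectory,
    read_xyz_trajectory,
    rmsd_series,
    rmsf_profile,
    write_pdb_trajectory,
    write_xyz_trajectory,
)


def _hbond_traj(frames):
    """Trajectory of donor/H/acceptor triples from (distance, angle) pairs."""
    atoms = [
        Atom(0, "N1", "N", 1, "LIG"),
        Atom(1, "H1", "H", 1, "LIG"),
        Atom(2, "O", "O", 2, "VAL"),
    ]
    coords = []
    for da, angle in frames:
        theta = math.radians(180.0 - angle)
        c = math.cos(theta)
        r = -c + math.sqrt(c * c + da**2 - 1.0)
        h = np.array([1.0, 0.0, 0.0])
        a = h + r * np.array([math.cos(theta), math.sin(theta), 0.0])
        coords.append([[0.0, 0.0, 0.0], h, a])
    return Trajectory(coords=np.asarray(coords), atoms=atoms)


SPEC = HBondSpec(donor_heavy=0, hydrogen=1, acceptor_heavy=2)


class TestHBondPresent:
    @pytest.mark.parametrize(
        "da,angle,expected",
        [
            (2.8, 170.0, True),   # comfortably bonded
            (3.2, 180.0, False),  # distance fails
            (2.8, 120.0, False),  # angle fails
            (3.0, 135.0, True),   # both thresholds exactly met — inclusive
        ],
    )
    def test_geometric_criteria(self, da, angle, expected):
        traj = _hbond_traj([(da, angle)])
        assert hbond_present(traj, 0, SPEC) is expected

    def test_missing_atom_raises(self):
        traj = _hbond_traj([(2.8, 170.0)])
        with pytest.raises(InvalidInputError, match="99"):
            hbond_present(traj, 0, HBondSpec(0, 1, 99))

    def test_degenerate_spec_rejected(self):
        with pytest.raises(InvalidInputError):
            HBondSpec(0, 0, 2)


class TestOccupancy:
    def test_all_bonded_frames(self):
        traj = _hbond_traj([(2.8, 170.0)] * 10)
        assert hbond_occupancy(traj, SPEC).occupancy_percent == 100.0

    def test_planted_46_percent(self):
        frames = [(2.8, 170.0)] * 46 + [(3.5, 170.0)] * 54
        occ = hbond_occupancy(_hbond_traj(frames), SPEC)
        assert occ.n_present == 46
        assert occ.occupancy_percent == pytest.approx(46.0)

    def test_single_frame_is_all_or_nothing(self):
        assert hbond_occupancy(_hbond_traj([(2.8, 170.0)]), SPEC).occupancy_percent == 100.0
        assert hbond_occupancy(_hbond_traj([(3.5, 170.0)]), SPEC).occupancy_percent == 0.0

    def test_empty_trajectory_raises(self):
        traj = Trajectory(coords=np.empty((0, 3, 3)),
                          atoms=[Atom(i, "X", "C", 1, "UNK") for i in range(3)])
        with pytest.raises(InvalidInputError):
            hbond_occupancy(traj, SPEC)

    def test_matches_brute_force_count(self, rng):
        frames = [(float(rng.uniform(2.5, 3.5)), float(rng.uniform(120, 180)))
                  for _ in range(200)]
        traj = _hbond_traj(frames)
        occ = hbond_occupancy(traj, SPEC)
        brute = sum(hbond_present(traj, f, SPEC) for f in range(200))
        assert occ.n_present == brute


class TestDistance:
    def test_static_pair(self):
        atoms = [Atom(0, "A", "C", 1, "X"), Atom(1, "B", "C", 1, "X")]
        coords = np.tile(np.array([[0.0, 0, 0], [3.0, 0, 0]]), (5, 1, 1))
        res = distance_series(Trajectory(coords=coords, atoms=atoms), 0, 1)
        assert np.allclose(res.values, 3.0)
        assert res.mean == pytest.approx(3.0)

    def test_two_frame_mean(self):
        atoms = [Atom(0, "A", "C", 1, "X"), Atom(1, "B", "C", 1, "X")]
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]],
                           [[0.0, 0, 0], [4.0, 0, 0]]])
        assert distance_series(Trajectory(coords=coords, atoms=atoms), 0, 1).mean \
            == pytest.approx(3.0)

    def test_identical_atoms_raise(self):
        atoms = [Atom(0, "A", "C", 1, "X"), Atom(1, "B", "C", 1, "X")]
        traj = Trajectory(coords=np.zeros((1, 2, 3)), atoms=atoms)
        with pytest.raises(InvalidInputError):
            distance_series(traj, 1, 1)

    def test_planted_noisy_mean_recovered(self, rng):
        n = 400
        planted = 9.7
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = planted + rng.normal(0, 0.3, n)
        atoms = [Atom(0, "NZ", "N", 89, "LYS"), Atom(1, "C0", "C", 1, "CRB")]
        res = distance_series(Trajectory(coords=coords, atoms=atoms), 0, 1)
        se = res.values.std(ddof=1) / math.sqrt(n)
        assert abs(res.mean - planted) < 3 * se


def _brute_force_rmsd(mobile, ref):
    """Independent oracle: minimise RMSD over rotation vectors numerically."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec)
        return np.sqrt(np.mean(np.sum((r.apply(mob_c) - ref_c) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(0)
    for start in [np.zeros(3), *rng.uniform(-np.pi, np.pi, (20, 3))]:
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestRmsd:
    def test_identity_frame_is_zero(self, rng):
        coords = rng.normal(size=(1, 5, 3))
        atoms = [Atom(i, "CA", "C", i, "GLY") for i in range(5)]
        traj = Trajectory(coords=coords, atoms=atoms)
        assert rmsd_series(traj, coords[0], list(range(5)))[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed(self, rng):
        ref = rng.normal(size=(6, 3))
        rot = Rotation.from_euler("zyx", [0.4, -1.2, 2.0])
        moved = rot.apply(ref) + np.array([10.0, -4.0, 7.0])
        atoms = [Atom(i, "CA", "C", i, "GLY") for i in range(6)]
        traj = Trajectory(coords=moved[None], atoms=atoms)
        assert rmsd_series(traj, ref, list(range(6)))[0] < 1e-8

    def test_matches_brute_force_minimisation(self):
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.0, 1.5, 0]])
        frame = ref.copy()
        frame[2, 1] += 0.3  # one atom displaced
        atoms = [Atom(i, "CA", "C", i, "GLY") for i in range(3)]
        traj = Trajectory(coords=frame[None], atoms=atoms)
        got = rmsd_series(traj, ref, [0, 1, 2])[0]
        assert got == pytest.approx(_brute_force_rmsd(frame, ref), abs=1e-6)

    def test_invariant_under_global_rigid_transform(self, rng):
        traj = generate_fluct_traj(8, np.full(10, 0.2), seed=4)
        sel = list(range(10))
        ref = traj.coords[0].copy()
        base = rmsd_series(traj, ref, sel)
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        moved = Trajectory(coords=traj.coords @ rot.T + np.array([5.0, -3.0, 2.0]),
                           atoms=traj.atoms)
        assert np.max(np.abs(rmsd_series(moved, ref, sel) - base)) < 1e-8

    def test_reference_shape_mismatch_raises(self):
        traj = generate_fluct_traj(3, np.full(4, 0.1), seed=0)
        with pytest.raises(InvalidInputError):
            rmsd_series(traj, np.zeros((3, 3)), [0, 1, 2, 3])

    def test_empty_selection_raises(self):
        traj = generate_fluct_traj(3, np.full(4, 0.1), seed=0)
        with pytest.raises(InvalidInputError):
            rmsd_series(traj, np.zeros((0, 3)), [])


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        traj = generate_fluct_traj(5, np.zeros(8), seed=0)
        assert np.allclose(rmsf_profile(traj, list(range(8))), 0.0)

    def test_isotropic_jitter_gives_sigma_sqrt3(self):
        sigma = np.full(60, 0.05)
        sigma[25] = 0.5
        traj = generate_fluct_traj(1200, sigma, seed=7)
        prof = rmsf_profile(traj, list(range(60)))
        assert prof[25] == pytest.approx(0.5 * math.sqrt(3), rel=0.05)

    def test_planted_flexible_loop_peak_localises(self):
        """A poly-glycine-like high-σ stretch (residues 42–48) must carry
        the profile maximum."""
        sigma = np.full(60, 0.1)
        sigma[41:48] = 0.8  # residues 42–48, 0-based slice
        traj = generate_fluct_traj(400, sigma, seed=8)
        prof = rmsf_profile(traj, list(range(60)))
        assert 41 <= int(np.argmax(prof)) <= 47
        assert prof[41:48].min() > prof[np.r_[0:35, 52:60]].max()

    def test_frame_order_invariance(self, rng):
        traj = generate_fluct_traj(50, np.full(12, 0.3), seed=9)
        prof = rmsf_profile(traj, list(range(12)))
        perm = rng.permutation(50)
        shuffled = Trajectory(coords=traj.coords[perm], atoms=traj.atoms)
        assert np.allclose(rmsf_profile(shuffled, list(range(12))), prof, atol=1e-10)

    def test_single_frame_raises(self):
        traj = generate_fluct_traj(1, np.full(5, 0.1), seed=0)
        with pytest.raises(InvalidInputError):
            rmsf_profile(traj, list(range(5)))


class TestTrajectoryContainer:
    def test_atom_count_mismatch_raises(self):
        with pytest.raises(InvalidInputError):
            Trajectory(coords=np.zeros((2, 3, 3)),
                       atoms=[Atom(0, "A", "C", 1, "X")])

    def test_nonfinite_coordinates_raise(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            Trajectory(coords=coords,
                       atoms=[Atom(0, "A", "C", 1, "X"), Atom(1, "B", "C", 1, "X")])

    def test_backbone_selection(self):
        atoms = [Atom(0, "N", "N", 1, "ALA"), Atom(1, "CA", "C", 1, "ALA"),
                 Atom(2, "CB", "C", 1, "ALA"), Atom(3, "C", "C", 1, "ALA"),
                 Atom(4, "O", "O", 1, "ALA")]
        traj = Trajectory(coords=np.zeros((1, 5, 3)), atoms=atoms)
        assert traj.select_ids(names=("N", "CA", "C", "O")) == [0, 1, 3, 4]


class TestTrajectoryIO:
    def test_pdb_roundtrip(self, tmp_path):
        traj = generate_fluct_traj(4, np.full(6, 0.2), seed=3)
        p = tmp_path / "traj.pdb"
        write_pdb_trajectory(traj, p)
        back = read_pdb_trajectory(p)
        assert back.n_frames == 4 and back.n_atoms == 6
        assert np.allclose(back.coords, traj.coords, atol=1.5e-3)  # %8.3f grid
        assert [a.id for a in back.atoms] == [a.id for a in traj.atoms]
        assert [a.name for a in back.atoms] == [a.name for a in traj.atoms]

    def test_xyz_roundtrip(self, tmp_path):
        traj = generate_fluct_traj(3, np.full(5, 0.2), seed=2)
        p = tmp_path / "traj.xyz"
        write_xyz_trajectory(traj, p)
        back = read_xyz_trajectory(p)
        assert back.n_frames == 3 and back.n_atoms == 5
        assert np.allclose(back.coords, traj.coords, atol=1e-7)

    def test_truncated_xyz_raises(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\nframe 0\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(InvalidInputError):
            read_xyz_trajectory(p)
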