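"""Trajectory descriptors: tilt, contacts, persistence, compactness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amphiprof.synthetic import TrajectorySpec, generate_helix_trajectory
from amphiprof.trajectory import (
    Trajectory,
    align_frames_to_x,
    compactness_series,
    contact_series,
    helix_axis,
    max_persistence,
    min_distance_series,
    read_trajectory,
    tilt_angle,
    top_contacts,
    write_trajectory,
)


def _toy_traj(coords, chains=None, dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    chains = chains or ["protein"] * n_atoms
    atoms = pd.DataFrame(
        {
            "atom_name": ["CA" if c == "protein" else "P" for c in chains],
            "res_id": list(range(1, n_atoms + 1)),
            "res_name": ["ALA" if c == "protein" else "PE" for c in chains],
            "chain": chains,
            "lipid_class": ["" if c == "protein" else "PE" for c in chains],
            "element": ["C" if c == "protein" else "P" for c in chains],
            "heavy": [True] * n_atoms,
            "phosphate": [c == "lipid" for c in chains],
        }
    )
    return Trajectory(coords=coords, atoms=atoms, dt=dt)


def ideal_helix(n=24, twist=100.0, rise=0.15, radius=0.23):
    i = np.arange(n)
    x = rise * i - rise * (n - 1) / 2
    phi = np.radians(twist * i)
    return np.column_stack([x, radius * np.cos(phi), radius * np.sin(phi)])


def rot_y(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), 0, -np.sin(a)], [0, 1, 0], [np.sin(a), 0, np.cos(a)]])


class TestHelixAxis:
    def test_collinear_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        assert np.allclose(helix_axis(pts, [0, 1, 2, 3]), [1, 0, 0])

    def test_orientation_follows_index_order(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        assert np.allclose(helix_axis(pts, [3, 2, 1, 0]), [-1, 0, 0])

    def test_recovers_known_axis_within_2_degrees(self):
        pts = ideal_helix() @ rot_y(25.0).T
        axis = helix_axis(pts, list(range(24)))
        truth = rot_y(25.0) @ np.array([1.0, 0.0, 0.0])
        angle = np.degrees(np.arccos(np.clip(axis @ truth, -1, 1)))
        assert angle < 2.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            helix_axis(np.zeros((5, 3)), [0, 1])

    def test_degenerate_cloud(self):
        with pytest.raises(ValueError):
            helix_axis(np.ones((4, 3)), [0, 1, 2, 3])


class TestTiltAngle:
    def test_in_plane_axis_zero(self):
        pts = ideal_helix()
        traj = _toy_traj(pts[None])
        assert tilt_angle(traj).alpha[0] == pytest.approx(0.0, abs=0.5)

    def test_rotated_30_degrees_up(self):
        pts = ideal_helix() @ rot_y(30.0).T
        traj = _toy_traj(pts[None])
        assert tilt_angle(traj).alpha[0] == pytest.approx(30.0, abs=0.5)

    def test_mirror_flips_sign_exactly(self):
        up = ideal_helix() @ rot_y(17.0).T
        down = up.copy()
        down[:, 2] = -down[:, 2]
        a_up = tilt_angle(_toy_traj(up[None])).alpha[0]
        a_down = tilt_angle(_toy_traj(down[None])).alpha[0]
        assert a_down == pytest.approx(-a_up, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        theta=st.floats(-180, 180),
        shift=st.tuples(
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
        ),
    )
    def test_invariant_under_z_rotation_and_translation(self, theta, shift):
        pts = ideal_helix() @ rot_y(12.0).T
        base = tilt_angle(_toy_traj(pts[None])).alpha[0]
        t = np.radians(theta)
        rz = np.array(
            [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
        )
        moved = pts @ rz.T + np.asarray(shift)
        assert tilt_angle(_toy_traj(moved[None])).alpha[0] == pytest.approx(
            base, abs=1e-6
        )


class TestMinDistance:
    def test_unit_distance(self):
        coords = np.array([[[0, 0, 0], [0, 0, 1.0]]])
        traj = _toy_traj(coords, chains=["protein", "lipid"])
        assert min_distance_series(traj, [0], [1])[0] == pytest.approx(1.0)

    def test_symmetric_in_selections(self, rng):
        coords = rng.normal(size=(4, 12, 3))
        traj = _toy_traj(coords)
        a, b = list(range(5)), list(range(5, 12))
        assert np.allclose(
            min_distance_series(traj, a, b), min_distance_series(traj, b, a)
        )

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(100):
            coords = rng.normal(size=(3, 12, 3))
            traj = _toy_traj(coords)
            a, b = list(range(5)), list(range(5, 12))
            series = min_distance_series(traj, a, b)
            for t in range(3):
                brute = min(
                    np.linalg.norm(coords[t, i] - coords[t, j]) for i in a for j in b
                )
                assert series[t] == pytest.approx(brute, abs=1e-12)

    def test_minimum_image_convention(self):
        coords = np.array([[[0.1, 0.0, 0.0], [3.9, 0.0, 0.0]]])
        traj = _toy_traj(coords, chains=["protein", "lipid"])
        traj.box = np.array([4.0, 4.0, 4.0])
        assert min_distance_series(traj, [0], [1], use_pbc=True)[0] == pytest.approx(0.2)

    def test_empty_selection(self):
        traj = _toy_traj(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError):
            min_distance_series(traj, [], [0])


class TestContactSeries:
    def test_cutoff_is_strict(self):
        d = np.array([0.45, 0.449, 10.0])
        assert list(contact_series(d)) == [False, True, False]

    def test_monotone_in_cutoff(self, rng):
        d = rng.uniform(0, 1, size=200)
        counts = [contact_series(d, c).sum() for c in (0.6, 0.45, 0.3, 0.1)]
        assert counts == sorted(counts, reverse=True)


class TestMaxPersistence:
    @pytest.mark.parametrize(
        "series,dt,expected",
        [
            ([True, True, False, True], 1.0, 2.0),
            ([True] * 5, 0.5, 2.5),
            ([False, False], 1.0, 0.0),
            ([], 1.0, 0.0),
        ],
    )
    def test_known_cases(self, series, dt, expected):
        assert max_persistence(np.array(series, dtype=bool), dt) == expected

    def test_matches_run_length_scan_oracle(self, rng):
        for _ in range(100):
            s = rng.random(1000) < 0.4
            best = run = 0
            for v in s:
                run = run + 1 if v else 0
                best = max(best, run)
            assert max_persistence(s, 1.0) == best * 1.0

    def test_bounded_by_true_count_and_duration(self, rng):
        s = rng.random(500) < 0.3
        p = max_persistence(s, 2.0)
        assert p <= s.sum() * 2.0 <= 500 * 2.0


class TestSyntheticTrajectoryRecovery:
    def test_zero_jitter_tilt_exact(self):
        spec = TrajectorySpec(n_frames=5, tilt_mean=30.0, tilt_sd=0.0, coord_noise=0.0)
        traj, truth = generate_helix_trajectory(spec, seed=42)
        ts = tilt_angle(traj)
        assert np.all(np.abs(ts.alpha - 30.0) < 0.5)

    def test_mean_tilt_recovery_with_jitter(self):
        spec = TrajectorySpec(n_frames=1000, tilt_mean=5.0, tilt_sd=7.5)
        traj, truth = generate_helix_trajectory(spec, seed=42)
        ts = tilt_angle(traj)
        assert abs(ts.mean - 5.0) < 2 * 7.5 / np.sqrt(1000)
        assert np.all(np.abs(ts.alpha) <= 90.0)

    def test_scripted_episode_recovered_exactly(self):
        spec = TrajectorySpec(
            n_frames=30,
            tilt_sd=0.0,
            coord_noise=0.0,
            contact_episodes=((5, "PE", 3, 10),),
        )
        traj, truth = generate_helix_trajectory(spec, seed=42)
        contacts = top_contacts(traj, k=10)
        assert len(contacts) == 1
        c = contacts[0]
        assert (c.res_id, c.lipid_class) == (5, "PE")
        assert c.max_persistence == 7.0  # 7 frames * 1 ns

    def test_scripted_ranking_matches_ground_truth(self):
        spec = TrajectorySpec(
            n_frames=50,
            tilt_sd=0.0,
            coord_noise=0.0,
            contact_episodes=(
                (5, "PE", 0, 40),
                (9, "PC", 10, 25),
                (12, "PI", 20, 27),
                (2, "PE", 30, 33),
            ),
        )
        traj, _ = generate_helix_trajectory(spec, seed=42)
        ranked = [(c.res_id, c.lipid_class, c.max_persistence) for c in top_contacts(traj)]
        assert ranked == [(5, "PE", 40.0), (9, "PC", 15.0), (12, "PI", 7.0), (2, "PE", 3.0)]

    def test_overlapping_episodes_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merging"):
            traj, truth = generate_helix_trajectory(
                TrajectorySpec(
                    n_frames=20,
                    tilt_sd=0.0,
                    coord_noise=0.0,
                    contact_episodes=((5, "PE", 0, 8), (5, "PE", 5, 12)),
                ),
                seed=42,
            )
        assert truth["episodes"][0]["spans"] == [(0, 12)]
        c = top_contacts(traj, k=1)[0]
        assert c.max_persistence == 12.0


class TestCompactness:
    def test_coincident_atoms_zero(self):
        coords = np.zeros((2, 3, 3))
        coords[:, 2] = [5, 5, 5]
        traj = _toy_traj(coords)
        assert compactness_series(traj, 1, [2])[0] == 0.0

    def test_static_trajectory_constant(self, rng):
        frame = rng.normal(size=(6, 3))
        traj = _toy_traj(np.repeat(frame[None], 4, axis=0))
        series = compactness_series(traj, 1, [4, 5, 6])
        assert np.allclose(series, series[0])

    def test_matches_brute_force(self, rng):
        coords = rng.normal(size=(5, 8, 3))
        traj = _toy_traj(coords)
        series = compactness_series(traj, 1, [5, 6, 7])
        for t in range(5):
            brute = min(np.linalg.norm(coords[t, 0] - coords[t, j]) for j in (4, 5, 6))
            assert series[t] == pytest.approx(brute, abs=1e-12)


class TestAlignment:
    def test_aligned_frame_unchanged(self):
        pts = ideal_helix() @ rot_y(10.0).T
        traj = _toy_traj(pts[None])
        aligned = align_frames_to_x(traj)
        twice = align_frames_to_x(aligned)
        assert np.allclose(aligned.coords, twice.coords, atol=1e-9)

    def test_y_axis_rotated_minus_90(self):
        pts = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0], [0, 3, 0.0]])
        traj = _toy_traj(pts[None])
        aligned = align_frames_to_x(traj)
        assert np.allclose(
            aligned.coords[0], [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], atol=1e-9
        )

    def test_projection_on_x_and_tilt_invariance(self, rng):
        pts = ideal_helix() @ rot_y(20.0).T
        t = np.radians(73.0)
        rz = np.array(
            [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
        )
        traj = _toy_traj((pts @ rz.T)[None])
        before = tilt_angle(traj).alpha
        aligned = align_frames_to_x(traj)
        axis = helix_axis(aligned.coords[0], list(range(24)))
        assert abs(axis[1]) < 1e-9
        assert axis[0] > 0
        assert np.allclose(tilt_angle(aligned).alpha, before, atol=1e-9)


class TestPDBRoundTrip:
    def test_two_models_ten_atoms(self, tmp_path):
        coords = np.arange(2 * 10 * 3, dtype=float).reshape(2, 10, 3) / 100.0
        traj = _toy_traj(coords, chains=["protein"] * 5 + ["lipid"] * 5)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, frame_interval=1.0)
        assert back.n_frames == 2
        assert back.n_atoms == 10
        # PDB stores 0.001 A precision; coords are nm
        assert np.allclose(back.coords, coords, atol=1e-4)
        assert list(back.atoms["chain"]) == ["protein"] * 5 + ["lipid"] * 5
        assert back.atoms["phosphate"].tolist() == [False] * 5 + [True] * 5

    def test_inconsistent_models_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        lines = ["MODEL     1"]
        for i in range(3):
            lines.append(
                f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    {1.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
        lines += ["ENDMDL", "MODEL     2"]
        for i in range(2):
            lines.append(
                f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    {1.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
        lines += ["ENDMDL", "END"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError):
            read_trajectory(path, frame_interval=1.0)


def test_invalid_dt_rejected():
    with pytest.raises(ValueError):
        _toy_traj(np.zeros((1, 4, 3)), dt=0.0)
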