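"""Trajectory statistics: superposition, RMSD, H-bonds, dihedrals, zinc."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acecleave.traj import (
    HBondSpec,
    SelectorError,
    Trajectory,
    circular_mean_deg,
    dihedral,
    dihedral_series,
    hbond_populations,
    read_pdb_trajectory,
    read_xyz_trajectory,
    rmsd_series,
    select_atoms,
    superpose_kabsch,
    synth_trajectory,
    zinc_geometry_check,
)

from conftest import make_test_trajectory, write_multimodel_pdb


def _random_rotation(rng):
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


class TestKabsch:
    def test_identical_frames_zero_rmsd_identity_rotation(self):
        frame = make_test_trajectory(1, 10).coords[0]
        rot, trans, rmsd = superpose_kabsch(frame, frame)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)

    def test_rigid_copy_superposes_exactly(self):
        rng = np.random.default_rng(1)
        ref = make_test_trajectory(1, 15, seed=2).coords[0]
        mobile = ref @ _random_rotation(rng).T + np.array([3.0, -1.0, 7.0])
        _, _, rmsd = superpose_kabsch(ref, mobile)
        assert rmsd <= 1e-9

    def test_kabsch_beats_rotation_grid_oracle(self):
        """No rotation from a 10^4-sample grid fits better than Kabsch."""
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(10, 3))
        mobile = rng.normal(size=(10, 3))
        _, _, best = superpose_kabsch(ref, mobile)
        ref_c = ref - ref.mean(axis=0)
        mob_c = mobile - mobile.mean(axis=0)
        for _ in range(10_000):
            rot = _random_rotation(rng)
            rmsd = np.sqrt(np.mean(np.sum((mob_c @ rot.T - ref_c) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(12, 3))
        mobile = ref.copy()
        mobile[:, 0] *= -1  # mirrored structure
        rot, _, _ = superpose_kabsch(ref, mobile)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_or_collinear_atoms_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose_kabsch(line[:2], line[:2])
        with pytest.raises(ValueError, match="collinear"):
            superpose_kabsch(line, line)


class TestRmsdSeries:
    def test_first_frame_is_zero(self):
        traj = make_test_trajectory(5, 20, seed=4)
        series = rmsd_series(traj)
        assert series[0] == pytest.approx(0.0, abs=1e-12)

    def test_jittered_frames_match_closed_form(self):
        """Isotropic jitter sigma on every atom gives RMSD ~ sigma*sqrt(3)."""
        rng = np.random.default_rng(11)
        base = rng.normal(0.0, 5.0, size=(100, 3))
        sigma = 0.2
        coords = np.concatenate(
            [
                base[None],
                base[None] + rng.normal(0.0, sigma, size=(500, 100, 3)),
            ]
        )
        traj = Trajectory(make_test_trajectory(1, 100).atoms, coords)
        series = rmsd_series(traj)[1:]
        assert float(np.mean(series)) == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_invariant_under_rigid_motion_of_whole_trajectory(self):
        rng = np.random.default_rng(5)
        traj = make_test_trajectory(6, 25, seed=6)
        series = rmsd_series(traj)
        rot = _random_rotation(rng)
        moved = Trajectory(traj.atoms, traj.coords @ rot.T + np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(rmsd_series(moved), series, atol=1e-9)

    def test_empty_trajectory_gives_empty_series(self):
        traj = make_test_trajectory(1, 5)
        empty = Trajectory(traj.atoms, traj.coords[:0])
        assert rmsd_series(empty).size == 0


def _hbond_template():
    atoms = pd.DataFrame(
        {
            "name": ["N", "H", "O", "CA", "CB", "CC"],
            "resname": ["HIS", "HIS", "ALA", "HIS", "ALA", "ALA"],
            "resid": [6, 6, 332, 6, 332, 332],
            "chain": ["P", "P", "E", "P", "E", "E"],
        }
    )
    coords = np.array(
        [[[0, 0, 0], [1, 0, 0], [3, 0, 0], [0, 1.5, 0], [4, 2, 1], [5, -1, 2]]],
        dtype=float,
    )
    return Trajectory(atoms, coords)


class TestHBonds:
    spec = HBondSpec("P:6:N", "P:6:H", "E:332:O")

    def test_population_matches_schedule(self):
        template = _hbond_template()
        schedule = np.zeros(100, dtype=bool)
        schedule[:60] = True
        traj = synth_trajectory(template, {self.spec: schedule}, jitter_sigma=0.02)
        (pop,) = hbond_populations(traj, [self.spec])
        assert pop.population == pytest.approx(0.60)

    def test_all_on_gives_unity(self):
        template = _hbond_template()
        traj = synth_trajectory(
            template, {self.spec: np.ones(40, dtype=bool)}, jitter_sigma=0.0
        )
        (pop,) = hbond_populations(traj, [self.spec])
        assert pop.population == 1.0

    def test_boundary_distance_counts_as_satisfied(self):
        """A donor-acceptor distance exactly at the cutoff is included."""
        template = _hbond_template()
        traj = synth_trajectory(
            template,
            {self.spec: np.ones(1, dtype=bool)},
            jitter_sigma=0.0,
            on_distance=self.spec.distance_cutoff,
        )
        (pop,) = hbond_populations(traj, [self.spec])
        assert pop.population == 1.0

    def test_concatenation_gives_frame_weighted_mean(self):
        template = _hbond_template()
        a = synth_trajectory(template, {self.spec: np.ones(30, dtype=bool)})
        b = synth_trajectory(
            template, {self.spec: np.zeros(70, dtype=bool)}, seed=1
        )
        (pa,) = hbond_populations(a, [self.spec])
        (pb,) = hbond_populations(b, [self.spec])
        (pc,) = hbond_populations(a.concat(b), [self.spec])
        expected = (30 * pa.population + 70 * pb.population) / 100
        assert pc.population == pytest.approx(expected, abs=1e-12)

    def test_unresolvable_selector_named_in_error(self):
        template = _hbond_template()
        bad = HBondSpec("P:99:N", "P:6:H", "E:332:O")
        with pytest.raises(SelectorError, match="P:99:N"):
            hbond_populations(template, [bad])

    def test_same_seed_reproduces_trajectory(self):
        template = _hbond_template()
        sched = {self.spec: np.ones(10, dtype=bool)}
        a = synth_trajectory(template, sched, jitter_sigma=0.1, seed=9)
        b = synth_trajectory(template, sched, jitter_sigma=0.1, seed=9)
        assert np.array_equal(a.coords, b.coords)


def _chain_trajectory(coords, names, resids):
    atoms = pd.DataFrame(
        {
            "name": names,
            "resname": ["GLY"] * len(names),
            "resid": resids,
            "chain": ["A"] * len(names),
        }
    )
    return Trajectory(atoms, np.asarray(coords, dtype=float)[None])


class TestDihedrals:
    def test_planar_trans_chain_is_180(self):
        """An extended zigzag chain has psi = 180 by convention."""
        coords = [
            [0.0, 0.0, 0.0],   # N1
            [1.0, 1.0, 0.0],   # CA1
            [2.0, 0.0, 0.0],   # C1
            [3.0, 1.0, 0.0],   # N2
        ]
        traj = _chain_trajectory(coords, ["N", "CA", "C", "N"], [1, 1, 1, 2])
        series = dihedral_series(traj, 1, "psi")
        assert abs(series[0]) == pytest.approx(180.0, abs=1e-9)

    def test_cis_coplanar_is_zero(self):
        coords = [
            [0.0, 0.0, 0.0],
            [1.0, 1.0, 0.0],
            [2.0, 0.0, 0.0],
            [1.0, -1.0, 0.0],
        ]
        assert dihedral(*coords) == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_normal_vector_oracle(self):
        """Independent formula: atan2 over plane normals, signed by b2."""
        rng = np.random.default_rng(21)
        for _ in range(200):
            p = rng.normal(size=(4, 3))
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            x = n1 @ n2
            y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
            expected = np.degrees(np.arctan2(y, x))
            assert dihedral(*p) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_rigid_motion_and_scaling(self):
        rng = np.random.default_rng(22)
        p = rng.normal(size=(4, 3))
        ref = dihedral(*p)
        rot = _random_rotation(rng)
        moved = p @ rot.T + np.array([5.0, -2.0, 1.0])
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)
        assert dihedral(*(3.7 * p)) == pytest.approx(ref, abs=1e-9)

    def test_phi_uses_previous_residue_carbonyl(self):
        coords = [
            [0.0, 0.0, 0.0],   # C of residue 5
            [1.0, 1.0, 0.0],   # N of residue 6
            [2.0, 0.0, 0.0],   # CA of residue 6
            [3.0, 1.0, 0.0],   # C of residue 6
        ]
        traj = _chain_trajectory(coords, ["C", "N", "CA", "C"], [5, 6, 6, 6])
        series = dihedral_series(traj, 6, "phi")
        assert abs(series[0]) == pytest.approx(180.0, abs=1e-9)

    def test_circular_mean_wraps_correctly(self):
        angles = np.array([178.0, -178.0])
        assert abs(circular_mean_deg(angles)) == pytest.approx(180.0, abs=1e-9)


def _zinc_trajectory(n_frames=1, jitter=0.0, seed=0, pull_index=None):
    rng = np.random.default_rng(seed)
    d = 2.1
    # regular tetrahedron vertices
    verts = d * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3)
    base = np.vstack([[0.0, 0.0, 0.0], verts])
    frames = base[None] + rng.normal(0.0, jitter, size=(n_frames, 5, 3))
    frames[:, 0] = 0.0  # zinc fixed at origin
    if pull_index is not None:
        frames[:, pull_index] *= 4.0 / d
    atoms = pd.DataFrame(
        {
            "name": ["ZN", "NE2", "NE2", "OE1", "OW"],
            "resname": ["ZN", "HIS", "HIS", "GLU", "HOH"],
            "resid": [1, 361, 365, 389, 500],
            "chain": ["Z", "E", "E", "E", "W"],
        }
    )
    return Trajectory(atoms, frames)


class TestZincGeometry:
    ligands = ["E:361:NE2", "E:365:NE2", "E:389:OE1", "W:500:OW"]

    def test_ideal_tetrahedron_retained_zero_deviation(self):
        table = zinc_geometry_check(_zinc_trajectory(), "Z:1:ZN", self.ligands)
        assert bool(table["retained"].iloc[0])
        assert table["angle_deviation"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_pulled_ligand_breaks_retention(self):
        table = zinc_geometry_check(
            _zinc_trajectory(pull_index=1), "Z:1:ZN", self.ligands
        )
        assert not bool(table["retained"].iloc[0])

    def test_small_jitter_retains_most_frames(self):
        """sigma=0.05 A thermal jitter keeps >99% of 1000 frames."""
        table = zinc_geometry_check(
            _zinc_trajectory(n_frames=1000, jitter=0.05, seed=42),
            "Z:1:ZN",
            self.ligands,
        )
        assert float(table["retained"].mean()) > 0.99

    def test_wrong_ligand_count_rejected(self):
        with pytest.raises(ValueError):
            zinc_geometry_check(_zinc_trajectory(), "Z:1:ZN", self.ligands[:3])


class TestReaders:
    def test_multimodel_pdb_round_trip(self, tmp_path):
        traj = make_test_trajectory(3, 8, seed=13)
        traj.atoms["name"] = [f"C{i}" for i in range(8)]
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(path, traj)
        back = read_pdb_trajectory(path)
        assert back.n_frames == 3 and back.n_atoms == 8
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)
        assert select_atoms(back, "A:3:C2").size == 1

    def test_xyz_round_trip(self, tmp_path):
        traj = make_test_trajectory(2, 4, seed=14)
        path = tmp_path / "traj.xyz"
        with open(path, "w") as fh:
            for f in range(2):
                fh.write("4\nframe\n")
                for i in range(4):
                    x, y, z = traj.coords[f, i]
                    fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")
        back = read_xyz_trajectory(path)
        assert back.n_frames == 2 and back.n_atoms == 4
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-5)

    def test_rmsd_agrees_with_mdanalysis(self, tmp_path):
        """Independent cross-check of the Kabsch RMSD against MDAnalysis."""
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        traj = make_test_trajectory(2, 10, seed=15)
        theirs = mda_rms.rmsd(
            traj.coords[1], traj.coords[0], center=True, superposition=True
        )
        _, _, ours = superpose_kabsch(traj.coords[0], traj.coords[1])
        assert ours == pytest.approx(theirs, abs=1e-6)
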