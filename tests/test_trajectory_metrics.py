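"""Trajectory observables: superposition, Rg, RMSF, SASA, occupancy, SDF."""

import numpy as np
import pandas as pd
import pytest

from barriereng.structure_io import Atom, CatalyticSite, Residue, Structure
from barriereng.synthetic import (
    GeneratorConfig,
    build_toy_protein,
    simulate_trajectory,
)
from barriereng.trajectory_metrics import (
    AnalysisWindow,
    Trajectory,
    distance_series,
    kabsch,
    radius_of_gyration,
    rmsf,
    sasa,
    site_occupancy,
    spatial_distribution,
    superpose,
)

from conftest import cloud_structure, random_rotation


def _site(traj, manifest) -> CatalyticSite:
    ser = traj.structure.find_residue("A", manifest["ser_seq_id"])
    return CatalyticSite(ser=ser)


@pytest.fixture(scope="module")
def scheduled_traj():
    cfg = GeneratorConfig(seed=11, duration_ns=20.0, n_ligands=4, n_waters=8,
                          occupancy_schedule=[(10.0, 20.0, 2)], protein_sigma=0.1)
    protein = build_toy_protein(cfg)
    traj, manifest = simulate_trajectory(protein, cfg)
    return traj, manifest


class TestKabschSuperpose:
    def test_identical_frames_zero_rmsd(self):
        pts = np.random.default_rng(0).normal(size=(10, 3)) * 4
        _, _, rmsd = kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3)) * 5
        R = random_rotation(rng)
        moved = pts @ R.T + np.array([5.0, 0.0, 0.0])
        _, _, rmsd = kabsch(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_mdanalysis_oracle(self, seed):
        """Post-fit RMSD equals the quaternion-based reference value."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3)) * 4
        b = rng.normal(size=(10, 3)) * 4
        _, _, ours = kabsch(a, b)
        theirs = mda_rmsd(a, b, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_superpose_structure_api(self):
        res = [Residue("A", i + 1, "ALA",
                       [Atom("CA", "C", [float(i) * 3, 0, 0], i + 1)])
               for i in range(4)]
        ref = Structure(models=[res])
        moved_res = [Residue("A", i + 1, "ALA",
                             [Atom("CA", "C", [float(i) * 3, 0, 5.0], i + 1)])
                     for i in range(4)]
        frame = Structure(models=[moved_res])
        fitted, rmsd = superpose(frame, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fitted.residues(0)[0].atoms[0].coords,
                                   [0, 0, 0], atol=1e-9)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        s = cloud_structure(np.array([[1.0, 2.0, 3.0]]))
        assert radius_of_gyration(s) == 0.0

    def test_two_unit_mass_atoms(self):
        """Two equal-mass atoms 2 Å apart: Rg = 1 Å (closed form)."""
        s = cloud_structure(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert radius_of_gyration(s) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 3)) * 6
        s = cloud_structure(pts)  # all carbon -> equal masses
        com = pts.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1)))
        assert radius_of_gyration(s) == pytest.approx(expected)


class TestRMSF:
    def test_static_trajectory_all_zero(self):
        cfg = GeneratorConfig(seed=5, duration_ns=5.0, n_ligands=1, n_waters=1,
                              protein_sigma=0.0)
        traj, _ = simulate_trajectory(build_toy_protein(cfg), cfg)
        table = rmsf(traj, AnalysisWindow(0.0, 5.0))
        assert np.allclose(table["rmsf"], 0.0, atol=1e-9)

    def test_single_oscillating_residue(self):
        """One residue oscillating ±1 Å along x has RMSF exactly 1."""
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [10.0, 10.0, 0],
                         [5.0, 5.0, 10.0]])
        models = []
        for k in range(10):
            dx = 1.0 if k % 2 == 0 else -1.0
            model = []
            for i, p in enumerate(base):
                xyz = p.copy()
                if i == 4:
                    xyz[0] += dx
                model.append(Residue("A", i + 1, "ALA",
                                     [Atom("CA", "C", xyz, i + 1)]))
            models.append(model)
        traj = Trajectory(structure=Structure(models=models),
                          times=np.arange(10) * 0.5)
        static = [("A", i, "") for i in range(1, 5)]
        table = rmsf(traj, AnalysisWindow(0.0, 4.5), fit_keys=static)
        assert table["rmsf"].iloc[4] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(table["rmsf"].iloc[:4], 0.0, atol=1e-6)

    def test_matches_brute_force(self):
        """RMSF equals the direct per-residue formula on a random-walk fixture."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(6, 3)) * 8
        coords = base + rng.normal(0, 0.3, size=(12, 6, 3)).cumsum(axis=0) * 0.1
        models = [
            [Residue("A", i + 1, "ALA", [Atom("CA", "C", coords[k, i], i + 1)])
             for i in range(6)]
            for k in range(12)
        ]
        traj = Trajectory(structure=Structure(models=models),
                          times=np.arange(12) * 0.5)
        table = rmsf(traj, AnalysisWindow(0.0, 5.5))
        # brute force with the same two-pass superposition protocol
        raw = coords.copy()
        ref = raw[0]
        fitted = np.empty_like(raw)
        for k in range(12):
            R, t, _ = kabsch(raw[k], ref)
            fitted[k] = raw[k] @ R.T + t
        mean = fitted.mean(axis=0)
        for k in range(12):
            R, t, _ = kabsch(raw[k], mean)
            fitted[k] = raw[k] @ R.T + t
        mean = fitted.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
        np.testing.assert_allclose(table["rmsf"], expected, atol=1e-9)

    def test_short_window_rejected(self, scheduled_traj):
        traj, _ = scheduled_traj
        with pytest.raises(ValueError):
            rmsf(traj, AnalysisWindow(0.0, 0.4))


class TestSASA:
    def test_isolated_oxygen_analytic(self):
        """Free O atom: SASA = 4π(1.52 + 1.4)² within 2% at 960 points."""
        s = cloud_structure(np.zeros((1, 3)), element="O", res_name="HOH")
        total, _ = sasa(s, n_points=960)
        assert total == pytest.approx(4 * np.pi * (1.52 + 1.4) ** 2, rel=0.02)

    def test_point_count_convergence(self):
        s = cloud_structure(np.zeros((1, 3)), element="O", res_name="HOH")
        analytic = 4 * np.pi * (1.52 + 1.4) ** 2
        errs = [abs(sasa(s, n_points=n)[0] - analytic) / analytic
                for n in (64, 960)]
        assert errs[1] <= errs[0]
        assert errs[1] < 0.02

    def test_coincident_atoms_count_once(self):
        s = cloud_structure(np.zeros((2, 3)))
        total_pair, _ = sasa(s)
        total_single, _ = sasa(cloud_structure(np.zeros((1, 3))))
        assert total_pair == pytest.approx(total_single)

    def test_buried_atom_near_zero(self):
        from conftest import fibonacci_shell

        shell = fibonacci_shell(200, 3.2)
        pts = np.vstack([np.zeros(3), shell])
        s = cloud_structure(pts)
        _, table = sasa(s)
        assert table.loc[table.seq_id == 1, "sasa"].item() == pytest.approx(0.0, abs=1.0)

    def test_too_few_points_rejected(self):
        s = cloud_structure(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            sasa(s, n_points=8)


class TestSiteOccupancy:
    def test_scheduled_window_reproduced(self, scheduled_traj):
        """Counts match the generator's occupancy schedule exactly."""
        traj, manifest = scheduled_traj
        site = _site(traj, manifest)
        occ = site_occupancy(traj, AnalysisWindow(10.0, 20.0), site, "ligand")
        assert (occ.counts == 2).all()
        occ0 = site_occupancy(traj, AnalysisWindow(0.5, 9.5), site, "ligand")
        assert (occ0.counts == 0).all()

    def test_counts_bounded_by_molecules(self, scheduled_traj):
        traj, manifest = scheduled_traj
        site = _site(traj, manifest)
        for species, n in [("ligand", 4), ("water", 8)]:
            occ = site_occupancy(traj, AnalysisWindow(0.0, 20.0), site, species)
            assert (occ.counts <= n).all()

    def test_bin_means_reproduce_step_schedule(self):
        """0 ligands for the first half, 2 for the second, in 10 ns bins."""
        cfg = GeneratorConfig(seed=13, duration_ns=40.0, n_ligands=3, n_waters=4,
                              occupancy_schedule=[(20.0, 40.0, 2)])
        traj, manifest = simulate_trajectory(build_toy_protein(cfg), cfg)
        site = _site(traj, manifest)
        occ = site_occupancy(traj, AnalysisWindow(0.0, 40.0), site, "ligand")
        bins = occ.bin_means(10.0).set_index("bin_start_ns")["mean_count"]
        assert bins.loc[0.0] == 0.0 and bins.loc[10.0] < 0.1
        assert bins.loc[20.0] == pytest.approx(2.0, abs=0.01)
        assert bins.loc[30.0] == pytest.approx(2.0, abs=0.01)

    def test_unknown_species_rejected(self, scheduled_traj):
        traj, manifest = scheduled_traj
        with pytest.raises(ValueError):
            site_occupancy(traj, AnalysisWindow(0.0, 20.0),
                           _site(traj, manifest), "lipid")


class TestDistanceSeries:
    def test_constant_for_parked_ligand(self, scheduled_traj):
        traj, manifest = scheduled_traj
        site = _site(traj, manifest)
        df = distance_series(traj, site, traj.ligand_ids[0])
        assert {"time_ns", "d_og_c7", "d_og_c10"} <= set(df.columns)
        assert len(df) == traj.n_frames

    def test_monotone_approach(self):
        """A ligand moved linearly toward the site gives decreasing distances."""
        ser = Residue("A", 1, "SER", [Atom("OG", "O", [0.0, 0, 0], 1)])
        models = []
        for k in range(8):
            lig = Residue("L", 1, "BHT", [
                Atom("C7", "C", [20.0 - 2 * k, 0, 0], 2),
                Atom("C10", "C", [25.0 - 2 * k, 0, 0], 3),
            ], is_hetatm=True)
            models.append([Residue("A", 1, "SER",
                                   [Atom("OG", "O", [0.0, 0, 0], 1)]), lig])
        traj = Trajectory(structure=Structure(models=models),
                          times=np.arange(8) * 0.5,
                          ligand_ids=[("L", 1, "")])
        site = CatalyticSite(ser=traj.structure.find_residue("A", 1))
        df = distance_series(traj, site, ("L", 1, ""))
        assert (np.diff(df["d_og_c7"]) < 0).all()
        np.testing.assert_allclose(df["d_og_c7"], 20.0 - 2 * np.arange(8))

    def test_equals_direct_euclidean(self, scheduled_traj):
        traj, manifest = scheduled_traj
        site = _site(traj, manifest)
        lig_key = traj.ligand_ids[1]
        df = distance_series(traj, site, lig_key)
        i = 7
        og = traj.structure.find_residue("A", manifest["ser_seq_id"],
                                         model=i).atom("OG").coords
        lig = traj.structure.find_residue(*lig_key, model=i)
        assert df["d_og_c7"].iloc[i] == pytest.approx(
            np.linalg.norm(lig.atom("C7").coords - og))


class TestSpatialDistribution:
    def _two_state_traj(self):
        """Ligand alternates between two fixed positions; protein static."""
        prot = [Residue("A", i + 1, "ALA",
                        [Atom("CA", "C", [float(i) * 4, 0, 0], i + 1)])
                for i in range(4)]
        models = []
        for k in range(10):
            pos = [30.0, 30.0, 30.0] if k % 2 == 0 else [40.0, 40.0, 40.0]
            lig = Residue("L", 1, "BHT", [Atom("C1", "C", pos, 99)], is_hetatm=True)
            models.append([Residue(r.chain, r.seq_id, r.res_name,
                                   [Atom(a.name, a.element, a.coords.copy(), a.serial)
                                    for a in r.atoms]) for r in prot] + [lig])
        return Trajectory(structure=Structure(models=models),
                          times=np.arange(10) * 0.5, ligand_ids=[("L", 1, "")])

    def test_parked_species_single_voxel(self):
        traj = self._two_state_traj()
        # restrict to even frames: ligand parked at one site
        grid = spatial_distribution(traj, AnalysisWindow(0.0, 4.5), "ligand",
                                    spacing=1.0)
        assert grid.values.max() == pytest.approx(0.5)

    def test_two_state_hopping_half_occupancy(self):
        """Half the frames in each of two voxels -> two voxels at 0.5."""
        traj = self._two_state_traj()
        grid = spatial_distribution(traj, AnalysisWindow(0.0, 4.5), "ligand",
                                    spacing=1.0)
        occupied = np.sort(grid.values[grid.values > 0])
        np.testing.assert_allclose(occupied, [0.5, 0.5])

    def test_absent_species_rejected(self):
        traj = self._two_state_traj()
        with pytest.raises(ValueError):
            spatial_distribution(traj, AnalysisWindow(0.0, 4.5), "water")

    def test_fractions_bounded(self, scheduled_traj):
        traj, _ = scheduled_traj
        grid = spatial_distribution(traj, AnalysisWindow(10.0, 20.0), "ligand",
                                    spacing=2.0)
        assert grid.values.min() >= 0.0 and grid.values.max() <= 1.0

    def test_cube_output(self, tmp_path, scheduled_traj):
        traj, _ = scheduled_traj
        grid = spatial_distribution(traj, AnalysisWindow(10.0, 20.0), "ligand",
                                    spacing=2.0)
        path = tmp_path / "sdf.cube"
        grid.write_cube(path)
        lines = path.read_text().splitlines()
        assert len(lines) > 6
        nx = int(lines[3].split()[0])
        assert nx == grid.values.shape[0]


class TestTrajectoryIO:
    def test_pdb_round_trip(self, tmp_path, scheduled_traj):
        from barriereng.structure_io import write_structure

        traj, manifest = scheduled_traj
        path = tmp_path / "traj.pdb"
        write_structure(traj.structure, path)
        loaded = Trajectory.from_pdb(path, frame_interval_ns=0.5)
        assert loaded.n_frames == traj.n_frames
        assert len(loaded.ligand_ids) == len(traj.ligand_ids)
        site = CatalyticSite(
            ser=loaded.structure.find_residue("A", manifest["ser_seq_id"]))
        occ = site_occupancy(loaded, AnalysisWindow(10.0, 20.0), site, "ligand")
        assert (occ.counts == 2).all()
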