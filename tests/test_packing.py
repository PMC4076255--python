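"""Area per lipid, density profiles, d-spacing, and the RDF vs oracles."""
import numpy as np
import pytest

from lamtraj.geometry import minimum_image_distance
from lamtraj.model import AnalysisWindow, AtomRecord, TopologyRoleMap, Trajectory
from lamtraj.packing import (
    compute_area_per_lipid,
    compute_local_density_profile,
    compute_rdf,
    extract_d_spacing,
    rdf_by_carbon,
)
from lamtraj.synth import make_density_trajectory, make_hex_lattice_slab


def brute_force_rdf(ref, tgt, box, bin_width, r_max, same_selection):
    """Independent O(N^2) pair count with the spherical-shell normalisation."""
    n_bins = int(np.ceil(r_max / bin_width))
    counts = np.zeros(n_bins)
    n_pairs = 0
    for i in range(len(ref)):
        for j in range(len(tgt)):
            if same_selection and i == j:
                continue
            r = float(minimum_image_distance(ref[i], tgt[j], box))
            n_pairs += 1
            k = int(r / bin_width)
            if k < n_bins:
                counts[k] += 1
    centers = (np.arange(n_bins) + 0.5) * bin_width
    volume = float(np.prod(box))
    rho = (n_pairs / len(ref)) / volume
    shell = 4 * np.pi * centers**2 * bin_width
    return counts / (len(ref) * rho * shell)


class TestArea:
    def test_exact_arithmetic(self):
        traj = Trajectory(
            np.zeros((1, 1, 3)), [[50.0, 50.0, 60.0]], [0.0], ["C71"]
        )
        res = compute_area_per_lipid(traj, 64)
        assert res.mean == pytest.approx(39.0625, abs=0)

    def test_constant_box_zero_standard_error(self):
        traj = Trajectory(
            np.zeros((100, 1, 3)),
            np.tile([50.0, 50.0, 60.0], (100, 1)),
            np.arange(100.0),
            ["C71"],
        )
        res = compute_area_per_lipid(traj, 64, AnalysisWindow(0, 100, blocks=5))
        assert res.se == 0.0

    def test_rejects_nonpositive_lipid_count(self, three_atom_traj):
        with pytest.raises(ValueError):
            compute_area_per_lipid(three_atom_traj, 0)


def uniform_box_system(n_atoms=4000, seed=0):
    rng = np.random.default_rng(seed)
    box = np.array([20.0, 20.0, 40.0])
    coords = rng.uniform(0, 1, (1, n_atoms, 3)) * box
    role_map = TopologyRoleMap(
        1, [AtomRecord(0, "O1", "headgroup_atom") for _ in range(n_atoms)]
    )
    traj = Trajectory(coords, box[None], [0.0], ["O1"] * n_atoms)
    return traj, role_map


class TestDensityProfile:
    def test_uniform_atoms_flat_within_poisson_noise(self):
        traj, role_map = uniform_box_system()
        prof = compute_local_density_profile(traj, role_map, None, 1.0)
        counts = prof.profile["sugar"] * prof.box_area * prof.bin_width / 15.999
        expect = 4000 / len(counts)
        assert np.all(np.abs(counts - expect) < 3 * np.sqrt(expect) + 3)

    def test_single_atom_normalisation(self):
        box = np.array([10.0, 10.0, 20.0])
        traj = Trajectory(np.array([[[5.0, 5.0, 7.3]]]), box[None], [0.0], ["O1"])
        role_map = TopologyRoleMap(1, [AtomRecord(0, "O1", "headgroup_atom")])
        prof = compute_local_density_profile(traj, role_map, None, 0.5)
        occupied = np.nonzero(prof.profile["sugar"])[0]
        assert len(occupied) == 1
        dz = prof.bin_width
        assert prof.profile["sugar"][occupied[0]] == pytest.approx(
            15.999 / (100.0 * dz)
        )

    def test_mass_conservation_each_frame(self, small_system):
        traj, role_map, _, _ = small_system
        prof = compute_local_density_profile(
            traj, role_map, AnalysisWindow(0, traj.n_frames, blocks=1), 0.5
        )
        total = prof.profile["total"].sum() * prof.bin_width * prof.box_area
        assert total == pytest.approx(role_map.masses.sum(), rel=1e-9)

    def test_bin_width_guard(self, small_system):
        traj, role_map, _, _ = small_system
        with pytest.raises(ValueError, match="Lz/4"):
            compute_local_density_profile(traj, role_map, None, 100.0)


class TestDSpacing:
    def _delta_profile(self):
        lz, bw = 64.0, 0.5
        n = int(lz / bw)
        y = np.zeros(n)
        y[0] = 5.0  # z = 0
        y[int(32.0 / bw)] = 5.0  # z = 32
        centers = (np.arange(n) + 0.5) * bw
        from lamtraj.packing import DensityProfile

        return DensityProfile(
            z_centers=centers,
            bin_width=bw,
            block_profiles={"sugar": y[None]},
            box_area=100.0,
        )

    def test_delta_peaks(self):
        assert extract_d_spacing(self._delta_profile()) == pytest.approx(32.0)

    def test_generator_recovery_within_bin(self):
        traj, role_map = make_density_trajectory(
            41.9, 1.5, n_frames=5, noise_sd=0.5, seed=2
        )
        prof = compute_local_density_profile(traj, role_map, None, 0.5)
        assert extract_d_spacing(prof) == pytest.approx(41.9, abs=0.5)

    def test_flat_profile_raises(self):
        from lamtraj.packing import DensityProfile

        prof = DensityProfile(
            z_centers=np.arange(10) + 0.5,
            bin_width=1.0,
            block_profiles={"sugar": np.full((1, 10), 2.0)},
        )
        with pytest.raises(ValueError, match="flat"):
            extract_d_spacing(prof)

    def test_invariant_under_z_translation(self):
        traj, role_map = make_density_trajectory(
            32.2, 1.5, n_frames=4, noise_sd=0.5, seed=7
        )
        d0 = extract_d_spacing(
            compute_local_density_profile(traj, role_map, None, 0.5)
        )
        shifted = Trajectory(
            np.mod(traj.coords + np.array([0, 0, 11.3]), traj.box[0]),
            traj.box,
            traj.times,
            traj.atom_names,
        )
        d1 = extract_d_spacing(
            compute_local_density_profile(shifted, role_map, None, 0.5)
        )
        assert d1 == pytest.approx(d0, abs=0.5)


class TestRdf:
    def test_matches_brute_force_oracle_bin_for_bin(self):
        rng = np.random.default_rng(1)
        box = np.array([15.0, 15.0, 15.0])
        frames = rng.uniform(0, 1, (10, 200, 3)) * box
        got = compute_rdf(frames, frames, box, bin_width=0.25, r_max=7.0)
        want = np.mean(
            [
                brute_force_rdf(f, f, box, 0.25, 7.0, same_selection=True)
                for f in frames
            ],
            axis=0,
        )
        assert np.allclose(got.g, want, atol=1e-10)

    def test_ideal_gas_plateau(self):
        rng = np.random.default_rng(2)
        box = np.array([30.0, 30.0, 30.0])
        pts = rng.uniform(0, 1, (10000, 3)) * box
        res = compute_rdf(pts, pts, box, bin_width=0.1, r_max=6.0)
        sel = (res.r_centers >= 3.0) & (res.r_centers <= 5.0)
        # Poisson noise on the pair count in each shell
        n_per_shell = 10000 * 4 * np.pi * res.r_centers[sel] ** 2 * 0.1 * (
            10000 / box.prod()
        )
        z = (res.g[sel] - 1.0) * np.sqrt(n_per_shell)
        assert np.abs(z.mean()) < 3.0 / np.sqrt(sel.sum()) * 3

    def test_single_pair_normalisation(self):
        box = np.array([40.0, 40.0, 40.0])
        pts = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        res = compute_rdf(pts, pts, box, bin_width=0.5, r_max=10.0)
        k = int(4.0 / 0.5)
        want = brute_force_rdf(pts, pts, box, 0.5, 10.0, same_selection=True)
        assert np.nonzero(res.g)[0].tolist() == [k]
        assert res.g[k] == pytest.approx(want[k], rel=1e-12)

    def test_pair_count_conservation(self):
        """Sum of dN recovered from g equals the true mean pair count."""
        rng = np.random.default_rng(3)
        box = np.array([12.0, 12.0, 12.0])
        pts = rng.uniform(0, 1, (150, 3)) * box
        bw, rmax = 0.2, 5.9
        res = compute_rdf(pts, pts, box, bin_width=bw, r_max=rmax)
        rho = (len(pts) - 1) / box.prod()
        shell = 4 * np.pi * res.r_centers**2 * bw
        recovered = (res.g * shell * rho).sum() * len(pts)
        direct = 0
        for i in range(len(pts)):
            d = minimum_image_distance(pts[i], np.delete(pts, i, axis=0), box)
            direct += int((d < bw * len(res.g)).sum())
        assert recovered == pytest.approx(direct, rel=1e-9)

    def test_hexagonal_peak_with_jitter(self):
        frames = []
        for s in range(30):
            pts, box = make_hex_lattice_slab(5.1, 12, 0.3, seed=50 + s)
            frames.append(pts)
        res = compute_rdf(
            np.array(frames), np.array(frames), box, 0.1, r_max=10.0, mode="2d"
        )
        assert res.first_peak() == pytest.approx(5.1, abs=0.1 + 1e-9)

    def test_r_max_guard_and_empty_selection(self):
        box = np.array([10.0, 10.0, 10.0])
        pts = np.zeros((1, 3))
        with pytest.raises(ValueError, match="r_max"):
            compute_rdf(pts, pts, box, r_max=8.0)
        with pytest.raises(ValueError, match="empty"):
            compute_rdf(np.zeros((1, 0, 3)), pts, box)

    def test_same_lipid_pairs_excluded(self):
        """Intra-lipid exclusion removes the bonded C71-C72 contact at 1.53 Å."""
        from lamtraj.synth import LamellarSpec, make_lamellar_trajectory

        spec = LamellarSpec(
            lipids_per_leaflet=16,
            n_frames=1,
            gauche_p=0.0,
            tilt_modes=((0.0, 0.0, 1.0),),
            xy_jitter_sd=0.0,
            seed=0,
        )
        traj, role_map, _ = make_lamellar_trajectory(spec)
        ref = traj.coords[:, role_map.carbon_selection("C71"), :]
        tgt = traj.coords[:, role_map.carbon_selection("C72"), :]
        lip = role_map.lipid_ids[role_map.carbon_selection("C71")]
        bonded_bin = int(1.53 / 0.1)
        with_excl = compute_rdf(
            ref, tgt, traj.box[0], 0.1, r_max=10.0,
            ref_lipid_ids=lip, target_lipid_ids=lip,
        )
        without = compute_rdf(ref, tgt, traj.box[0], 0.1, r_max=10.0)
        assert with_excl.g[bonded_bin] == 0.0
        assert without.g[bonded_bin] > 0.0
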