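"""Gauche/trans populations, chain tilt, and protrusion classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamtraj.conformation import (
    chain_dihedral_labels,
    classify_conformer,
    classify_protruding,
    compute_chain_vectors,
    compute_gauche_profile,
    compute_tilt_distribution,
)
from lamtraj.leaflets import assign_leaflets
from lamtraj.model import AnalysisWindow, LeafletAssignment
from lamtraj.synth import LamellarSpec, make_lamellar_trajectory


class TestClassifier:
    @pytest.mark.parametrize(
        "theta,state",
        [
            (180.0, "trans"),
            (-150.0, "trans"),
            (60.0, "gauche_plus"),
            (-60.0, "gauche_minus"),
            (120.0, "trans"),  # documented tie-break at the boundary
            (-120.0, "trans"),
            (119.9, "gauche_plus"),
            (-119.9, "gauche_minus"),
        ],
    )
    def test_windows(self, theta, state):
        assert classify_conformer(theta) == state

    def test_population_sums_to_one(self, small_system):
        traj, role_map, truth, _ = small_system
        leaflets = LeafletAssignment(truth.leaflet_labels, truth.leaflet_normals)
        prof = compute_gauche_profile(traj, role_map, leaflets)
        assert np.allclose(prof.p_gauche + prof.p_trans, 1.0)
        assert np.allclose(
            prof.p_gauche, prof.p_gauche_plus + prof.p_gauche_minus
        )


class TestGaucheProfile:
    def test_labels_for_12_carbon_chain(self, small_system):
        _, role_map, _, _ = small_system
        labels = chain_dihedral_labels(role_map, "sn1")
        assert labels == [f"C{71 + k}-C{74 + k}" for k in range(9)]

    def test_all_trans_gives_exact_zero(self):
        spec = LamellarSpec(lipids_per_leaflet=4, n_frames=5, gauche_p=0.0, seed=8)
        traj, role_map, truth = make_lamellar_trajectory(spec)
        leaflets = LeafletAssignment(truth.leaflet_labels, truth.leaflet_normals)
        prof = compute_gauche_profile(traj, role_map, leaflets)
        assert np.all(prof.p_gauche == 0.0)

    def test_recovers_generating_probabilities(self, small_system):
        traj, role_map, truth, spec = small_system
        leaflets = LeafletAssignment(truth.leaflet_labels, truth.leaflet_normals)
        prof = compute_gauche_profile(traj, role_map, leaflets)
        p = 0.2
        sigma = np.sqrt(p * (1 - p) / prof.counts)
        assert np.all(np.abs(prof.p_gauche - p) < 3 * sigma + 1e-12)

    def test_estimator_is_unbiased_over_replicates(self):
        """Mean deviation from p over many replicates shrinks as 1/sqrt(R)."""
        p, reps = 0.25, 60
        estimates = []
        for r in range(reps):
            spec = LamellarSpec(
                lipids_per_leaflet=4, n_frames=8, gauche_p=p, seed=1000 + r
            )
            traj, role_map, truth = make_lamellar_trajectory(spec)
            leaflets = LeafletAssignment(
                truth.leaflet_labels, truth.leaflet_normals
            )
            prof = compute_gauche_profile(traj, role_map, leaflets)
            estimates.append(prof.chain_average())
        n_per_rep = 16 * 8 * 9
        sigma = np.sqrt(p * (1 - p) / n_per_rep)
        assert abs(np.mean(estimates) - p) < 3 * sigma / np.sqrt(reps)

    def test_empty_window_rejected(self, small_system):
        traj, role_map, truth, _ = small_system
        leaflets = LeafletAssignment(truth.leaflet_labels, truth.leaflet_normals)
        with pytest.raises(ValueError):
            compute_gauche_profile(
                traj, role_map, leaflets, AnalysisWindow(30, 31)
            )


class TestChainVectors:
    def test_straight_chain_along_z(self):
        spec = LamellarSpec(
            lipids_per_leaflet=1,
            n_leaflets=2,
            n_frames=1,
            gauche_p=0.0,
            tilt_modes=((0.0, 0.0, 1.0),),
            seed=0,
        )
        traj, role_map, truth = make_lamellar_trajectory(spec)
        v = compute_chain_vectors(traj, role_map)
        for lipid in range(2):
            sign = truth.leaflet_normals[truth.leaflet_labels[lipid] - 1]
            assert np.allclose(v[0, lipid], [0, 0, sign], atol=1e-9)

    def test_rigid_rotation_angle(self):
        spec = LamellarSpec(
            lipids_per_leaflet=1,
            n_leaflets=2,
            n_frames=1,
            gauche_p=0.0,
            tilt_modes=((24.0, 0.0, 1.0),),
            seed=0,
        )
        traj, role_map, truth = make_lamellar_trajectory(spec)
        v = compute_chain_vectors(traj, role_map)
        theta = np.degrees(np.arccos(np.clip(np.abs(v[0, :, 2]), -1, 1)))
        assert np.allclose(theta, 24.0, atol=1e-6)

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_tilt_of_vector_and_negation_sum_to_180(self, comps):
        v = np.array(comps)
        if np.linalg.norm(v) < 1e-3:
            return
        v = v / np.linalg.norm(v)
        t1 = np.degrees(np.arccos(np.clip(v[2], -1, 1)))
        t2 = np.degrees(np.arccos(np.clip(-v[2], -1, 1)))
        assert t1 + t2 == pytest.approx(180.0, abs=1e-6)


def _vectors_from_angles(theta_deg, rng):
    theta = np.radians(theta_deg)
    phi = rng.uniform(0, 2 * np.pi, size=np.shape(theta))
    return np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=-1,
    )


class TestTiltDistribution:
    def test_single_angle_single_peak_bin(self):
        rng = np.random.default_rng(0)
        v = _vectors_from_angles(np.full((5, 40), 18.0), rng)
        leaflets = LeafletAssignment(np.ones(40, dtype=int))
        dist = compute_tilt_distribution(v, leaflets, bin_width=2.0)
        assert dist.counts[1].sum() == 200
        assert abs(dist.peaks[1][0] - 18.0) <= 1.0

    def test_bimodal_peaks_recovered(self):
        rng = np.random.default_rng(1)
        theta = np.where(
            rng.random((50, 64)) < 0.5,
            rng.normal(24.0, 3.0, (50, 64)),
            rng.normal(156.0, 3.0, (50, 64)),
        )
        v = _vectors_from_angles(theta, rng)
        leaflets = LeafletAssignment(np.ones(64, dtype=int))
        dist = compute_tilt_distribution(v, leaflets, bin_width=2.0)
        top2 = sorted(dist.peaks[1][:2])
        assert abs(top2[0] - 24.0) <= 2.0
        assert abs(top2[1] - 156.0) <= 2.0

    def test_isotropic_follows_sine_density(self):
        rng = np.random.default_rng(2)
        n = 200000
        v = rng.normal(size=(1, n, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        leaflets = LeafletAssignment(np.ones(n, dtype=int))
        dist = compute_tilt_distribution(v, leaflets, bin_width=5.0)
        edges = np.arange(len(dist.bin_centers) + 1) * 5.0
        expect = n * (
            np.cos(np.radians(edges[:-1])) - np.cos(np.radians(edges[1:]))
        ) / 2.0
        resid = (dist.counts[1] - expect) / np.sqrt(np.maximum(expect, 1))
        assert np.all(np.abs(resid) < 4.0)
        assert dist.counts[1].sum() == n  # histogram mass conservation

    def test_histogram_mass_conservation_per_leaflet(self, small_system):
        traj, role_map, truth, _ = small_system
        v = compute_chain_vectors(traj, role_map)
        leaflets = LeafletAssignment(truth.leaflet_labels, truth.leaflet_normals)
        dist = compute_tilt_distribution(v, leaflets)
        for leaf, c in dist.counts.items():
            n_lipids = (truth.leaflet_labels == leaf).sum()
            assert c.sum() == traj.n_frames * n_lipids


class TestProtrusion:
    def test_all_aligned_zero_fraction(self):
        v = np.tile([0.0, 0.0, 1.0], (3, 10, 1))
        leaflets = LeafletAssignment(np.ones(10, dtype=int), normals=[1.0])
        assert classify_protruding(v, leaflets)[1] == 0.0

    def test_all_at_90_degrees_is_fraction_one(self):
        v = np.tile([1.0, 0.0, 0.0], (2, 8, 1))
        labels = np.repeat([1, 2], 4)
        leaflets = LeafletAssignment(labels, normals=[1.0, -1.0])
        frac = classify_protruding(v, leaflets)
        assert frac == {1: 1.0, 2: 1.0}

    def test_flipped_fraction_recovered(self):
        spec = LamellarSpec(
            lipids_per_leaflet=25,
            n_frames=40,
            tilt_modes=((15.0, 2.0, 0.9), (156.0, 3.0, 0.1)),
            seed=21,
        )
        traj, role_map, truth = make_lamellar_trajectory(spec)
        leaflets = assign_leaflets(traj, role_map)
        v = compute_chain_vectors(traj, role_map)
        frac = classify_protruding(v, leaflets)
        n = 25 * 40
        sigma = np.sqrt(0.1 * 0.9 / n)
        for leaf, f in frac.items():
            assert abs(f - 0.10) < 3 * sigma

    def test_threshold_validation(self):
        v = np.zeros((1, 1, 3))
        v[..., 2] = 1.0
        leaflets = LeafletAssignment(np.ones(1, dtype=int))
        with pytest.raises(ValueError):
            classify_protruding(v, leaflets, theta_lo=100.0, theta_hi=50.0)
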