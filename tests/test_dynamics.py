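"""P2 autocorrelation, exponential fits, correlation-time recovery."""
import numpy as np
import pytest

from lamtraj.dynamics import (
    acf_for_series,
    build_vector_series,
    compute_acf_p2,
    correlation_time_profile,
    fit_correlation_time,
)
from lamtraj.model import AnalysisWindow, AtomRecord, TopologyRoleMap, Trajectory
from lamtraj.synth import (
    RotDiffSpec,
    make_ch_diffusion_trajectory,
    simulate_rotational_diffusion,
)


def brute_force_c2(u, max_lag):
    """All-origins double loop over (t0, t) -- the definition, literally."""
    F = len(u)
    out = np.zeros(max_lag + 1)
    for lag in range(max_lag + 1):
        vals = []
        for t0 in range(F - lag):
            x = float(np.dot(u[t0], u[t0 + lag]))
            vals.append(1.5 * x * x - 0.5)
        out[lag] = np.mean(vals)
    return out


def ch_test_system(n_frames=4):
    """One lipid: C at origin, one H straight up -- for vector building."""
    template = [
        AtomRecord(0, "C1", "ring_anchor", anchor="C1"),
        AtomRecord(0, "C4", "ring_anchor", anchor="C4"),
        AtomRecord(0, "C1'", "ring_anchor", anchor="C1p"),
        AtomRecord(0, "C4'", "ring_anchor", anchor="C4p"),
        AtomRecord(0, "C71", "chain_carbon", chain="sn1"),
        AtomRecord(0, "H71A", "chain_hydrogen", parent="C71"),
    ]
    role_map = TopologyRoleMap.from_template(1, template)
    base = np.array(
        [
            [1.0, 0.0, 5.0],
            [2.0, 1.0, 4.0],
            [3.0, 0.0, 3.0],
            [4.0, 1.0, 2.0],
            [5.0, 5.0, 5.0],
            [5.0, 5.0, 6.09],
        ]
    )
    coords = np.tile(base, (n_frames, 1, 1))
    box = np.tile([20.0, 20.0, 20.0], (n_frames, 1))
    traj = Trajectory(coords, box, np.arange(n_frames, dtype=float),
                      [a.name for a in template])
    return traj, role_map


class TestVectorSeries:
    def test_ch_normalisation(self):
        traj, role_map = ch_test_system()
        series = build_vector_series(traj, role_map, "CH", carbon="C71")
        assert len(series) == 1
        assert np.allclose(series[0].vectors, [0.0, 0.0, 1.0], atol=1e-12)

    def test_ring_modes_are_anchor_differences(self):
        traj, role_map = ch_test_system()
        s12 = build_vector_series(traj, role_map, "ring12")[0]
        want = traj.coords[0][1] - traj.coords[0][2]  # C1' -> C4
        want = want / np.linalg.norm(want)
        assert np.allclose(s12.vectors[0], want, atol=1e-12)

    def test_ring_equivariance_under_rigid_rotation(self):
        traj, role_map = ch_test_system()
        from lamtraj.geometry import rotation_aligning

        R = rotation_aligning(
            np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        )
        rotated = Trajectory(
            traj.coords @ R.T + 8.0, traj.box, traj.times, traj.atom_names
        )
        v0 = build_vector_series(traj, role_map, "ring12")[0].vectors[0]
        v1 = build_vector_series(rotated, role_map, "ring12")[0].vectors[0]
        assert np.allclose(v1, R @ v0, atol=1e-10)

    def test_zero_length_vector_rejected(self):
        traj, role_map = ch_test_system()
        traj.coords[:, 5] = traj.coords[:, 4]  # H on top of C
        with pytest.raises(ValueError, match="zero-length"):
            build_vector_series(traj, role_map, "CH", carbon="C71")


class TestAcf:
    def test_frozen_vector_is_one(self):
        u = np.tile([0.6, 0.0, 0.8], (100, 1))
        c2 = compute_acf_p2(u)
        assert np.allclose(c2, 1.0, atol=1e-12)

    def test_iid_vectors_decorrelate(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=(4000, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        c2 = compute_acf_p2(u, max_lag=20)
        assert c2[0] == pytest.approx(1.0, abs=1e-12)
        # P2 of two independent uniform directions has mean 0, var 1/5
        se = np.sqrt(0.2 / 4000)
        assert np.all(np.abs(c2[1:]) < 3 * se * np.sqrt(5))

    def test_matches_brute_force_all_origins(self):
        rng = np.random.default_rng(5)
        u = simulate_rotational_diffusion(RotDiffSpec(0.01, 1.0, 300, 1, seed=6))[
            :, 0
        ]
        got = compute_acf_p2(u, max_lag=120)
        want = brute_force_c2(u, 120)
        assert np.allclose(got, want, atol=1e-10)

    def test_bounds_invariant(self):
        u = simulate_rotational_diffusion(RotDiffSpec(0.02, 1.0, 500, 8, seed=7))
        c2 = compute_acf_p2(u)
        assert c2[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(c2 >= -0.5 - 1e-9) and np.all(c2 <= 1.0 + 1e-9)

    def test_max_lag_guard(self):
        u = np.tile([0.0, 0.0, 1.0], (10, 1))
        with pytest.raises(ValueError):
            compute_acf_p2(u, max_lag=10)


class TestFit:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 50_000.0, 5.0)  # ps, sampled every 5 ps
        c2 = np.exp(-t / 10_000.0)  # tau = 10 ns
        res = fit_correlation_time(t, c2)
        assert res.tau_ns == pytest.approx(10.0, rel=1e-3)
        assert res.tau_analytic_ns == pytest.approx(10.0, rel=1e-3)
        assert not res.flagged

    def test_constant_curve_flagged_not_silent(self):
        t = np.arange(0.0, 100.0)
        res = fit_correlation_time(t, np.ones_like(t))
        assert res.flagged

    def test_tau_recovery_scaled(self):
        """tau = 1/(6 D_r) recovered within 10% from a moderate series."""
        tau_steps = 400.0
        d_r = 1.0 / (6.0 * tau_steps)
        u = simulate_rotational_diffusion(RotDiffSpec(d_r, 1.0, 20000, 40, seed=8))
        c2 = compute_acf_p2(u)
        res = fit_correlation_time(np.arange(len(c2), dtype=float), c2)
        assert res.tau_ns * 1000 == pytest.approx(tau_steps, rel=0.10)

    def test_sigma_covers_truth_across_replicates(self):
        """~95% coverage of the true tau by +/-1.96 sigma over replicates.

        100 replicates at reduced size; the pass bound 91/100 is the
        one-sided binomial acceptance region for a true coverage of 95%.
        """
        tau_steps = 300.0
        d_r = 1.0 / (6.0 * tau_steps)
        hits = 0
        for rep in range(100):
            u = simulate_rotational_diffusion(
                RotDiffSpec(d_r, 1.0, 4000, 16, seed=3000 + rep)
            )
            c2 = compute_acf_p2(u, max_lag=2000)
            per = np.stack(
                [compute_acf_p2(u[:, v], max_lag=2000) for v in range(16)]
            )
            res = fit_correlation_time(
                np.arange(2001, dtype=float), c2, per_series_c2=per
            )
            if abs(res.tau_ns * 1000 - tau_steps) <= 1.96 * res.sigma_tau_ns * 1000:
                hits += 1
        assert hits >= 91


class TestCorrelationTimeProfile:
    def test_flat_profile_for_uniform_rates(self):
        d_r = np.full(6, 1.0 / (6 * 200.0))
        traj, role_map = make_ch_diffusion_trajectory(
            d_r, n_lipids=8, n_frames=12000, dt_ps=1.0, seed=9
        )
        table = correlation_time_profile(traj, role_map, include_rings=False)
        taus = table["tau_ns"].to_numpy() * 1000
        assert np.all(np.abs(taus - 200.0) / 200.0 < 0.25)

    def test_monotone_rates_give_monotone_taus(self):
        taus_true = np.array([600.0, 300.0, 150.0, 75.0])
        d_r = 1.0 / (6 * taus_true)
        traj, role_map = make_ch_diffusion_trajectory(
            d_r, n_lipids=8, n_frames=16000, dt_ps=1.0, seed=10
        )
        table = correlation_time_profile(traj, role_map, include_rings=False)
        got = table["tau_ns"].to_numpy() * 1000
        assert np.all(np.diff(got) < 0)  # head-to-tail decrease
        assert np.all(np.abs(got - taus_true) / taus_true < 0.25)

    def test_ring_taus_from_driven_anchors(self):
        ring_tau = 250.0
        d_r = np.full(4, 1.0 / (6 * 100.0))
        traj, role_map = make_ch_diffusion_trajectory(
            d_r,
            n_lipids=8,
            n_frames=10000,
            dt_ps=1.0,
            seed=11,
            d_r_rings=(1 / (6 * ring_tau),) * 3,
        )
        table = correlation_time_profile(traj, role_map, include_rings=True)
        rings = table[table["label"].str.startswith("ring")]
        got = rings["tau_ns"].to_numpy() * 1000
        assert np.all(np.abs(got - ring_tau) / ring_tau < 0.3)

    def test_single_frame_rejected(self):
        d_r = np.full(4, 0.001)
        traj, role_map = make_ch_diffusion_trajectory(
            d_r, n_lipids=1, n_frames=2, dt_ps=1.0, seed=1
        )
        with pytest.raises(ValueError):
            correlation_time_profile(traj, role_map, AnalysisWindow(0, 1))
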