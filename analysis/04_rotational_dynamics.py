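"""Reorientational dynamics: C2(t) decay and correlation-time recovery.

Three demonstrations:
* isotropic rotational diffusion at literature-scale correlation times
  (45 ns for a near-headgroup C-H vector, 78 ns for the combined sugar
  rings, 160 ns of 5 ps frames) is recovered by the single-exponential
  fit + trapezoidal integration to within a few percent;
* a chain whose per-carbon diffusion rate increases toward the tail gives
  the head-to-tail decreasing tau profile;
* the three ring vectors (C1->C4, C1'->C4', C1'->C4) report their driven
  correlation times.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from lamtraj.dynamics import compute_acf_p2, correlation_time_profile, fit_correlation_time
from lamtraj.synth import (
    RotDiffSpec,
    make_ch_diffusion_trajectory,
    simulate_rotational_diffusion,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "dynamics"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, tau_ns in (("chain C71-H", 45.0), ("ring12", 78.0)):
        dt = 5.0
        d_r = 1.0 / (6.0 * tau_ns * 1000.0)
        u = simulate_rotational_diffusion(RotDiffSpec(d_r, dt, 32000, 128, seed=1))
        c2 = compute_acf_p2(u)
        res = fit_correlation_time(np.arange(len(c2)) * dt, c2, label=label)
        rows.append(
            {"label": label, "tau_true_ns": tau_ns, "tau_fit_ns": res.tau_ns}
        )
        print(f"{label}: true tau {tau_ns} ns -> fitted {res.tau_ns:.1f} ns")
    pd.DataFrame(rows).to_csv(OUT / "tau_recovery.csv", index=False)

    taus_true = np.array([600.0, 450.0, 300.0, 200.0, 130.0, 80.0])
    traj, role_map = make_ch_diffusion_trajectory(
        1.0 / (6 * taus_true), n_lipids=8, n_frames=12000, dt_ps=1.0, seed=2,
        d_r_rings=(1 / (6 * 900.0),) * 3,
    )
    table = correlation_time_profile(traj, role_map)
    table["tau_ps"] = table["tau_ns"] * 1000
    table.to_csv(OUT / "tau_profile.csv", index=False)
    chain = table[~table["label"].str.startswith("ring")]
    print("per-carbon tau profile (ps), head -> tail:")
    print("  true:  ", taus_true.tolist())
    print("  fitted:", [round(t) for t in chain["tau_ps"]])
    rings = table[table["label"].str.startswith("ring")]
    print("ring taus (true 900 ps):", [round(t) for t in rings["tau_ps"]])


if __name__ == "__main__":
    main()
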