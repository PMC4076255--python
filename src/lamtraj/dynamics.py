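"""Second-rank reorientational autocorrelation and correlation times.

For a unit vector mu(t) the second-rank autocorrelation is

    C2(t) = < P2( mu(t0) . mu(t0 + t) ) >_{t0},   P2(x) = (3 x^2 - 1) / 2,

averaged over all valid time origins (maximally overlapping windows) and
then over the vectors/lipids in the system.  For isotropic rotational
Brownian motion with diffusion coefficient D_r the closed form is
``C2(t) = exp(-6 D_r t)`` with correlation time ``tau = 1/(6 D_r)``.

The average C2 is fitted to a single exponential ``a exp(-t/tau_fit)``;
the reported correlation time is the trapezoidal integral of the fitted
curve on the lag grid plus the analytic tail ``a tau_fit exp(-t_max/tau_fit)``
beyond the last lag.  The direct analytic integral ``a tau_fit`` is kept
alongside for comparison; the two agree for well-sampled decays.  Fits are
unweighted and restricted to lags before C2 first drops below 0.05 (tail
noise dominates beyond), and a fit whose tau exceeds 100x the time window
is flagged rather than silently returned.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import minimum_image_displacement
from .model import AnalysisWindow, TopologyRoleMap, Trajectory

__all__ = [
    "VectorSeries",
    "build_vector_series",
    "compute_acf_p2",
    "AcfResult",
    "fit_correlation_time",
    "correlation_time_profile",
]

VECTOR_MODES = ("CH", "ring1", "ring2", "ring12", "chain_axis")

RING_ENDPOINTS = {
    "ring1": ("C1", "C4"),
    "ring2": ("C1p", "C4p"),
    "ring12": ("C1p", "C4"),
}


@dataclass
class VectorSeries:
    """A labelled unit-vector time series for one lipid (or one C-H bond)."""

    label: str
    vectors: np.ndarray  # (n_frames, 3), unit norm
    dt_ps: float

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        norms = np.linalg.norm(self.vectors, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError(f"{self.label}: vectors are not unit length")


def _bond_vectors(
    traj: Trajectory, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Normalised minimum-image vectors a -> b, shape (F, n, 3)."""
    d = np.stack(
        [
            minimum_image_displacement(
                traj.coords[f][idx_a], traj.coords[f][idx_b], traj.box[f]
            )
            for f in range(traj.n_frames)
        ]
    )
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        raise ValueError("zero-length vector in series")
    return d / norm


def build_vector_series(
    traj: Trajectory,
    role_map: TopologyRoleMap,
    mode: str,
    carbon: str | None = None,
    window: AnalysisWindow | None = None,
) -> list[VectorSeries]:
    """Unit-vector series for a rotational mode, one series per lipid.

    Modes: ``CH`` (C-H bonds of ``carbon``; one series per hydrogen per
    lipid), ``ring1`` (C1 -> C4), ``ring2`` (C1' -> C4'), ``ring12``
    (C1' -> C4), ``chain_axis`` (first-to-last carbon-pair midpoints).
    """
    if mode not in VECTOR_MODES:
        raise ValueError(f"unknown vector mode {mode!r}")
    sub = traj.window(window)
    dt = sub.dt_ps if sub.n_frames > 1 else 1.0
    series: list[VectorSeries] = []
    if mode == "CH":
        if carbon is None:
            raise ValueError("mode 'CH' needs a carbon name")
        pairs_a = []
        pairs_b = []
        labels = []
        for lipid in role_map.iter_lipids():
            c = role_map.carbon_index(lipid, carbon)
            for h in role_map.hydrogens_of(lipid, carbon):
                pairs_a.append(c)
                pairs_b.append(h)
                labels.append(f"{carbon}-H/{lipid}")
        if not pairs_a:
            raise ValueError(f"no hydrogens declared on carbon {carbon!r}")
        vec = _bond_vectors(sub, np.array(pairs_a), np.array(pairs_b))
        for i, lab in enumerate(labels):
            series.append(VectorSeries(lab, vec[:, i], dt))
    elif mode in RING_ENDPOINTS:
        a_lab, b_lab = RING_ENDPOINTS[mode]
        idx_a = np.array(
            [role_map.ring_anchor(l, a_lab) for l in role_map.iter_lipids()]
        )
        idx_b = np.array(
            [role_map.ring_anchor(l, b_lab) for l in role_map.iter_lipids()]
        )
        vec = _bond_vectors(sub, idx_a, idx_b)
        for lipid in role_map.iter_lipids():
            series.append(VectorSeries(f"{mode}/{lipid}", vec[:, lipid], dt))
    else:  # chain_axis
        from .conformation import compute_chain_vectors

        vec = compute_chain_vectors(sub, role_map, "sn1")
        for lipid in role_map.iter_lipids():
            series.append(VectorSeries(f"chain_axis/{lipid}", vec[:, lipid], dt))
    return series


def compute_acf_p2(
    vectors: np.ndarray, max_lag: int | None = None
) -> np.ndarray:
    """C2(t) for unit-vector series; all time origins; FFT-accelerated.

    ``vectors`` has shape (F, 3) or (F, V, 3); the result has length
    ``max_lag + 1`` (default F - 1 lags), averaged over the V series.

    Uses the tensor identity ``P2(u.v) = 3/2 sum_ij (u_i u_j)(v_i v_j) - 1/2``
    so each of the 9 product series can be autocorrelated with an FFT; the
    result is exactly the all-origins average (up to float rounding).
    """
    u = np.asarray(vectors, dtype=np.float64)
    if u.ndim == 2:
        u = u[:, None, :]
    F = u.shape[0]
    if max_lag is None:
        max_lag = F - 1
    if max_lag >= F:
        raise ValueError("max lag must be smaller than the series length")
    n_fft = 1
    while n_fft < 2 * F:
        n_fft *= 2
    acc = np.zeros(max_lag + 1)
    counts = F - np.arange(max_lag + 1, dtype=np.float64)
    V = u.shape[1]
    for v in range(V):
        q = np.einsum("fi,fj->fij", u[:, v], u[:, v]).reshape(F, 9)
        spec = np.fft.rfft(q, n=n_fft, axis=0)
        corr = np.fft.irfft((spec * spec.conj()).sum(axis=1), n=n_fft)
        acc += corr[: max_lag + 1]
    c2 = 1.5 * acc / (counts * V) - 0.5
    return c2


@dataclass
class AcfResult:
    """Fitted C2 curve with its correlation time."""

    label: str
    lag_ps: np.ndarray
    c2: np.ndarray
    amplitude: float
    tau_fit_ns: float  # decay constant of the fitted exponential
    tau_ns: float  # trapezoid integral of the fit (+ analytic tail)
    tau_analytic_ns: float  # a * tau_fit
    sigma_tau_ns: float
    flagged: bool = False


def fit_correlation_time(
    lag_ps: np.ndarray,
    c2: np.ndarray,
    label: str = "",
    per_series_c2: np.ndarray | None = None,
    fit_floor: float = 0.05,
) -> AcfResult:
    """Fit ``a exp(-t/tau)`` and integrate it into a correlation time (ns).

    ``per_series_c2`` (shape (n_series, n_lags)) feeds the per-lipid spread
    into ``sigma_tau``; the reported uncertainty is the larger of the fit
    covariance estimate and the spread-based standard error.
    """
    lag_ps = np.asarray(lag_ps, dtype=np.float64)
    c2 = np.asarray(c2, dtype=np.float64)
    if lag_ps.shape != c2.shape or c2.size < 3:
        raise ValueError("need >= 3 (lag, C2) points")
    if not np.all(np.isfinite(c2)):
        raise ValueError("C2 contains non-finite values")
    span = lag_ps[-1] - lag_ps[0]

    def _fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
        below = np.nonzero(y < fit_floor)[0]
        stop = int(below[0]) if below.size else len(y)
        stop = max(stop, 3)
        t_fit, y_fit = t[:stop], y[:stop]
        guess_tau = max(span / 3.0, t[1] - t[0] if len(t) > 1 else 1.0)
        popt, pcov = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t_fit,
            y_fit,
            p0=(max(y_fit[0], 1e-3), guess_tau),
            bounds=((1e-9, 1e-9), (2.0, np.inf)),
            maxfev=10000,
        )
        return float(popt[0]), float(popt[1]), pcov

    a, tau_fit, pcov = _fit(lag_ps, c2)
    flagged = tau_fit > 100.0 * max(span, lag_ps[1] - lag_ps[0])
    fitted = a * np.exp(-lag_ps / tau_fit)
    tau_ps = float(
        np.trapezoid(fitted, lag_ps) + a * tau_fit * np.exp(-lag_ps[-1] / tau_fit)
    )
    tau_analytic_ps = a * tau_fit
    # delta method on tau ~ a * tau_fit from the fit covariance
    sigma_fit = 0.0
    if np.all(np.isfinite(pcov)):
        grad = np.array([tau_fit, a])
        sigma_fit = float(np.sqrt(max(grad @ pcov @ grad, 0.0)))
    sigma_spread = 0.0
    if per_series_c2 is not None and per_series_c2.shape[0] > 1:
        taus = []
        for y in per_series_c2:
            try:
                ai, ti, _ = _fit(lag_ps, np.asarray(y, dtype=np.float64))
                taus.append(ai * ti)
            except RuntimeError:
                continue
        if len(taus) > 1:
            sigma_spread = float(
                np.std(taus, ddof=1) / np.sqrt(len(taus))
            )
    sigma = max(sigma_fit, sigma_spread)
    return AcfResult(
        label=label,
        lag_ps=lag_ps,
        c2=c2,
        amplitude=a,
        tau_fit_ns=tau_fit / 1000.0,
        tau_ns=tau_ps / 1000.0,
        tau_analytic_ns=tau_analytic_ps / 1000.0,
        sigma_tau_ns=sigma / 1000.0,
        flagged=bool(flagged),
    )


def acf_for_series(
    series: list[VectorSeries],
    max_lag: int | None = None,
    label: str = "",
    spread_sample: int = 32,
) -> AcfResult:
    """Average C2 over a set of series, then fit one correlation time.

    The per-lipid spread entering ``sigma_tau`` is estimated from (up to)
    ``spread_sample`` individual series to bound the cost on large systems.
    """
    if not series:
        raise ValueError("no vector series")
    F = min(s.vectors.shape[0] for s in series)
    if F < 2:
        raise ValueError("vector series needs at least two frames")
    if max_lag is None:
        max_lag = F - 1
    stack = np.stack([s.vectors[:F] for s in series], axis=1)
    c2 = compute_acf_p2(stack, max_lag=max_lag)
    dt = series[0].dt_ps
    lags = np.arange(max_lag + 1) * dt
    per = None
    if len(series) > 1:
        take = np.linspace(0, len(series) - 1, min(spread_sample, len(series)))
        per = np.stack(
            [
                compute_acf_p2(stack[:, int(i)], max_lag=max_lag)
                for i in np.unique(take.astype(int))
            ]
        )
    return fit_correlation_time(lags, c2, label=label, per_series_c2=per)


def correlation_time_profile(
    traj: Trajectory,
    role_map: TopologyRoleMap,
    window: AnalysisWindow | None = None,
    max_lag: int | None = None,
    include_rings: bool = True,
    chain: str = "sn1",
) -> pd.DataFrame:
    """Correlation time per chain carbon (C-H vectors) plus ring vectors.

    Each carbon's C2 is averaged over that carbon's hydrogens and all
    lipids before fitting.  Returns a DataFrame with columns
    ``label, tau_ns, sigma_tau_ns, amplitude, flagged``.
    """
    sub = traj.window(window)
    if sub.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation time")
    rows = []
    for carbon in role_map.chain_carbon_names(chain):
        series = build_vector_series(sub, role_map, "CH", carbon=carbon)
        res = acf_for_series(series, max_lag=max_lag, label=carbon)
        rows.append(res)
    if include_rings:
        for mode in ("ring1", "ring2", "ring12"):
            try:
                series = build_vector_series(sub, role_map, mode)
            except ValueError:
                continue
            rows.append(acf_for_series(series, max_lag=max_lag, label=mode))
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "tau_ns": [r.tau_ns for r in rows],
            "sigma_tau_ns": [r.sigma_tau_ns for r in rows],
            "amplitude": [r.amplitude for r in rows],
            "flagged": [r.flagged for r in rows],
        }
    )
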