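"""Kinetic, free-energy and relaxation analyses.

Transition counting with dwell confirmation, Arrhenius fits of escape
frequencies (ln nu = ln A - Ea/RT), acceleration factors rho = tau_u /
tau_b, histogram free-energy landscapes Delta F = -kB T ln(P/P_ref),
multi-exponential relaxation fits by variable projection, and a
dipole-fluctuation estimator of the static permittivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from pathmd.units import R_GAS


# ---------------------------------------------------------------------------
# transition kinetics
# ---------------------------------------------------------------------------

@dataclass
class TransitionResult:
    """Mean waiting time tau (ps), frequency nu = 1/tau, event count.

    ``n_events = 0`` marks an explicit no-transition outcome (tau and nu
    are None rather than NaN).
    """

    tau: float | None
    nu: float | None
    n_events: int
    crossing_times: np.ndarray = field(default_factory=lambda: np.empty(0))


def transition_times(times, values, threshold: float = 0.0,
                     dwell_time: float = 1.0) -> TransitionResult:
    """Mean waiting time between confirmed threshold crossings.

    A crossing of ``threshold`` counts only once the series has dwelt in
    the destination region for at least ``dwell_time`` (hysteresis), so a
    single noisy spike shorter than the dwell window is never counted as
    two events.  Waiting intervals are measured from the series start to
    the first confirmed crossing and between consecutive confirmed
    crossings.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    side = values > threshold
    crossings = []
    current = side[0]
    i = 1
    n = len(times)
    while i < n:
        if side[i] != current:
            # candidate crossing at times[i]: confirmed iff the series
            # dwells on the new side for dwell_time without flipping back
            dwell_ok = True
            j = i
            while j < n and times[j] - times[i] < dwell_time:
                if side[j] != side[i]:
                    dwell_ok = False
                    break
                j += 1
            if dwell_ok:
                crossings.append(times[i])
                current = side[i]
                i += 1
            else:
                i = j + 1 if j > i else i + 1
        else:
            i += 1
    if not crossings:
        return TransitionResult(tau=None, nu=None, n_events=0)
    waits = np.diff(np.concatenate([[times[0]], crossings]))
    tau = float(np.mean(waits))
    return TransitionResult(
        tau=tau, nu=1.0 / tau, n_events=len(crossings),
        crossing_times=np.asarray(crossings),
    )


@dataclass
class ArrheniusFit:
    """OLS fit of ln nu against 1/T: Ea (kJ/mol), ln A, R^2."""

    temperatures: np.ndarray
    transition_times: np.ndarray
    ea: float
    ln_a: float
    r_squared: float


def arrhenius_fit(temperatures, taus) -> ArrheniusFit:
    """Activation energy from escape times at several temperatures.

    Ordinary least squares of ln(1/tau) on 1/T; Ea = -slope * R with
    R = 8.314 J/mol/K, reported in kJ/mol.
    """
    T = np.asarray(temperatures, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if T.shape != tau.shape or T.ndim != 1 or len(T) < 2:
        raise ValueError("need matching 1-D arrays with >= 2 points")
    if np.any(tau <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and transition times must be positive")
    if len(np.unique(T)) < 2:
        raise ValueError("duplicate temperatures collapse the design")
    res = stats.linregress(1.0 / T, np.log(1.0 / tau))
    return ArrheniusFit(
        temperatures=T, transition_times=tau,
        ea=float(-res.slope * R_GAS), ln_a=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class AccelerationEstimate:
    tau_unbiased: float
    tau_biased: float
    rho: float
    ln_rho: float


def acceleration_factor(tau_unbiased: float, tau_biased: float) -> AccelerationEstimate:
    """rho = tau_u / tau_b, the factor by which biasing shortens the
    mean 2-state transition time."""
    if tau_unbiased <= 0 or tau_biased <= 0:
        raise ValueError("transition times must be positive")
    rho = tau_unbiased / tau_biased
    return AccelerationEstimate(
        tau_unbiased=float(tau_unbiased), tau_biased=float(tau_biased),
        rho=float(rho), ln_rho=float(np.log(rho)),
    )


# ---------------------------------------------------------------------------
# free-energy landscapes
# ---------------------------------------------------------------------------

@dataclass
class FELGrid:
    """Histogram free-energy grid in kBT units.

    ``delta_f`` is -ln(P/P_ref): with ``ref='max'`` the most probable bin
    sits at 0 and every other bin is positive; with ``ref='min'`` the
    literal minimal-probability reference is used and populated bins are
    <= 0 (deepest basins most negative, the usual landscape-figure
    convention).  Empty bins are masked (NaN).
    """

    edges: tuple
    counts: np.ndarray
    delta_f: np.ndarray
    ref: str
    p_min: float
    degenerate: bool = False


def free_energy_landscape(samples, bins, temperature: float, samples2=None,
                          ref: str = "max") -> FELGrid:
    """1-D or 2-D free-energy landscape from samples (kBT units)."""
    if ref not in ("max", "min"):
        raise ValueError("ref must be 'max' or 'min'")
    x = np.asarray(samples, dtype=float)
    if samples2 is not None:
        counts, ex, ey = np.histogram2d(x, np.asarray(samples2, dtype=float), bins=bins)
        edges = (ex, ey)
    else:
        counts, ex = np.histogram(x, bins=bins)
        edges = (ex,)
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples")
    p = counts / total
    occupied = p > 0
    degenerate = int(occupied.sum()) <= 1
    p_ref = p[occupied].max() if ref == "max" else p[occupied].min()
    delta_f = np.full(p.shape, np.nan)
    delta_f[occupied] = -np.log(p[occupied] / p_ref)
    return FELGrid(
        edges=edges, counts=counts, delta_f=delta_f, ref=ref,
        p_min=float(p[occupied].min()), degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# multi-exponential relaxation
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    """Amplitudes and rates of sum_m A_m exp(-k_m t), rate-descending."""

    amplitudes: np.ndarray
    rates: np.ndarray
    residual: float
    converged: bool


def _varpro_residual(log_k, t, y, m):
    k = np.exp(log_k)
    design = np.exp(-np.outer(t, k))
    amps, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ amps - y


def fit_multiexponential(times, values, m: int, n_starts: int = 10,
                         seed: int = 0, max_residual: float = np.inf) -> DecayFit:
    """Fit an M-mode exponential decay by variable projection.

    Rates are optimized in log space by least squares from ``n_starts``
    random restarts (seeded); amplitudes follow linearly at each step.
    Raises if no restart converges below ``max_residual``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if m < 1:
        raise ValueError("need at least one mode")
    if t.shape != y.shape or not np.all(np.isfinite(y)):
        raise ValueError("times and values must match and be finite")
    span = t.max() - t.min()
    if span <= 0:
        raise ValueError("degenerate time axis")
    rng = np.random.Generator(np.random.PCG64(seed))
    best = None
    # crude single-exponential scale to anchor the restarts
    k_scale = 1.0 / max(span / 3.0, 1e-12)
    for s in range(n_starts):
        if s == 0:
            log_k0 = np.log(k_scale * np.geomspace(0.2, 5.0, m))
        else:
            log_k0 = np.log(k_scale) + rng.uniform(-4, 3, size=m)
        try:
            sol = optimize.least_squares(
                _varpro_residual, log_k0, args=(t, y, m), method="lm", xtol=1e-14
            )
        except Exception:
            continue
        res = float(np.linalg.norm(sol.fun))
        if best is None or res < best[0]:
            best = (res, sol.x)
    if best is None:
        raise RuntimeError("multi-exponential fit failed to converge")
    res, log_k = best
    k = np.exp(log_k)
    design = np.exp(-np.outer(t, k))
    amps, *_ = np.linalg.lstsq(design, y, rcond=None)
    order = np.argsort(-k)
    converged = res <= max_residual
    if not converged:
        raise RuntimeError(
            f"multi-exponential fit residual {res:.3g} above tolerance "
            f"{max_residual:.3g}"
        )
    return DecayFit(
        amplitudes=np.asarray(amps)[order], rates=k[order],
        residual=res, converged=converged,
    )


# ---------------------------------------------------------------------------
# dipole fluctuation statistics
# ---------------------------------------------------------------------------

_E_CHARGE = 1.602176634e-19  # C
_EPS0 = 8.8541878128e-12  # F/m
_KB_J = 1.380649e-23  # J/K


def dipole_statistics(dipoles, volume: float, temperature: float):
    """Normalized dipole autocorrelation and fluctuation permittivity.

    ``dipoles`` is an (n_frames, 3) total-dipole series in e*nm,
    ``volume`` in nm^3.  eps(0) = 1 + (<M^2> - <M>^2) / (3 eps0 V kB T)
    (the standard dipole-fluctuation formula); a zero-variance series
    gives exactly eps(0) = 1 and an autocorrelation identically 1.
    """
    M = np.atleast_2d(np.asarray(dipoles, dtype=float))
    if M.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    mean = M.mean(axis=0)
    dM = M - mean
    var = float(np.sum(dM * dM) / M.shape[0])  # <|M|^2> - |<M>|^2
    n = M.shape[0]
    # relative threshold absorbs round-off from the mean subtraction
    if var <= 1e-24 * max(float(np.mean(M * M)), 1e-300):
        return np.ones(n), 1.0
    # direct-sum ACF of the fluctuation, normalized at lag 0
    acf = np.empty(n)
    denom = np.sum(dM * dM)
    for lag in range(n):
        acf[lag] = np.sum(dM[: n - lag] * dM[lag:]) / denom * n / (n - lag)
    # unit conversion: (e nm)^2 / (eps0 nm^3 kB T)
    fluct_si = var * (_E_CHARGE * 1e-9) ** 2
    denom_si = 3.0 * _EPS0 * (volume * 1e-27) * _KB_J * temperature
    eps0 = 1.0 + fluct_si / denom_si
    return acf, float(eps0)
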