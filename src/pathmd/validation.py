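"""End-to-end validation studies on the built-in systems.

These are the package's own benchmark experiments: equilibrium sampling
checks on the quartic double well, the bias-acceleration measurement
(escape-time ratio rho between matched unbiased and biased runs), and
the restraint-steering measurement on the bead chain.  The study
conditions are fixed here — double well a = 8 kJ/mol (a ~3 kBT barrier,
rare-event regime), friction 0.3/ps for the kinetics study; a 10-bead
chain with one 0.75 nm restraint spanning beads 0-9 for steering — and
run lengths are sized so a full study completes in minutes on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from pathmd.config import build_run, resolve_config
from pathmd.engine import run_trajectory
from pathmd.kinetics_analysis import free_energy_landscape, transition_times
from pathmd.restraints_io import RestraintRecord, fulfillment_report
from pathmd.units import KB


def _child_seed(seed: int, tag: int) -> int:
    # keep derived seeds well below 2**31
    return (seed * 9973 + tag) % 2_000_000_000


# ---------------------------------------------------------------------------
# equilibrium sampling of the double well
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannStudy:
    well_ratio: float
    well_ratio_se: float
    fel_max_dev_se_units: float
    n_samples: int


def boltzmann_double_well(seed: int = 0, n_walkers: int = 64,
                          n_steps: int = 200_000, a: float = 5.0,
                          b: float = 0.5, temperature: float = 300.0,
                          bins: int = 25) -> BoltzmannStudy:
    """Unbiased sampling of an ensemble of independent double-well walkers.

    Returns the right/left well population ratio with its standard error
    across walkers (the analytic value for the symmetric well is 1) and
    the worst per-bin deviation of the histogram free-energy profile from
    the analytic Boltzmann profile, in units of the per-bin standard
    error.
    """
    cfg = resolve_config({
        "seed": _child_seed(seed, 1),
        "system": {"name": "double_well_1d", "a": a, "b": b,
                   "n_particles": n_walkers},
        "integrator": {"friction": 1.0, "temperature_k": temperature},
        "bias": {"enabled": False},
    })
    system, integ, _, _ = build_run(cfg)
    traj = run_trajectory(system, integ, n_steps=n_steps, stride=20)
    burn = traj.n_frames // 10
    x = traj.positions[burn:, :, 0]  # (frames, walkers)

    right = (x > 0).mean(axis=0)  # per-walker right-well occupancy
    ratios = right / np.maximum(1.0 - right, 1e-12)
    well_ratio = float(ratios.mean())
    well_ratio_se = float(ratios.std(ddof=1) / np.sqrt(n_walkers))

    # thin to ~independent samples for the per-bin multinomial error
    thin = x[::20].ravel()  # 2 ps apart
    edges = np.linspace(-1.8 * b, 1.8 * b, bins + 1)
    grid = free_energy_landscape(thin, edges, temperature)
    beta = 1.0 / (KB * temperature)
    p_ref = np.empty(bins)
    for j in range(bins):
        xs = np.linspace(edges[j], edges[j + 1], 200)
        p_ref[j] = np.trapezoid(np.exp(-beta * a * ((xs / b) ** 2 - 1) ** 2), xs)
    p_ref /= p_ref.sum()
    f_ref = -np.log(p_ref / p_ref.max())
    occ = grid.counts > 50
    dev = grid.delta_f[occ] - f_ref[occ]
    dev = dev - dev.mean()  # profiles match up to an additive constant
    se = np.maximum(1.0 / np.sqrt(grid.counts[occ]), 5e-3)
    return BoltzmannStudy(
        well_ratio=well_ratio,
        well_ratio_se=well_ratio_se,
        fel_max_dev_se_units=float(np.max(np.abs(dev) / se)),
        n_samples=int(thin.size),
    )


# ---------------------------------------------------------------------------
# acceleration of barrier crossing
# ---------------------------------------------------------------------------

@dataclass
class AccelerationStudy:
    tau_unbiased: np.ndarray
    tau_biased: np.ndarray
    rho_per_pair: np.ndarray
    rho_pooled: float
    fraction_rho_ge_1: float
    mannwhitney_p: float
    n_pairs: int


def _escape_run(seed: int, biased: bool, n_steps: int, a: float,
                friction: float, dwell: float):
    over = {
        "seed": seed,
        "system": {"name": "double_well_1d", "a": a},
        "integrator": {"friction": friction},
    }
    if not biased:
        over["bias"] = {"enabled": False}
    cfg = resolve_config(over)
    system, integ, bias, _ = build_run(cfg)
    traj = run_trajectory(system, integ, bias_stack=bias, n_steps=n_steps, stride=4)
    res = transition_times(traj.times, traj.positions[:, 0, 0],
                           threshold=0.0, dwell_time=dwell)
    if res.n_events == 0:
        # censored: the run length is a lower bound on the waiting time
        return float(traj.times[-1]), np.array([traj.times[-1]])
    waits = np.diff(np.concatenate([[traj.times[0]], res.crossing_times]))
    return res.tau, waits


def acceleration_double_well(seed: int = 0, n_pairs: int = 20,
                             a: float = 8.0, friction: float = 0.3,
                             steps_unbiased: int = 600_000,
                             steps_biased: int = 100_000,
                             dwell: float = 1.0) -> AccelerationStudy:
    """Escape-time comparison: unbiased replicates vs default bias.

    The unbiased baselines are drawn as one ensemble run of ``n_pairs``
    independent walkers (statistically identical to separate runs, and
    long enough for a precise waiting time per walker); each walker is
    paired with its own biased run.  rho = tau_u / tau_b per pair, and
    the pooled waiting-time samples feed a one-sided Mann-Whitney test
    for accelerated crossing.
    """
    cfg = resolve_config({
        "seed": _child_seed(seed, 99),
        "system": {"name": "double_well_1d", "a": a, "n_particles": n_pairs},
        "integrator": {"friction": friction},
        "bias": {"enabled": False},
    })
    system, integ, _, _ = build_run(cfg)
    ens = run_trajectory(system, integ, n_steps=steps_unbiased, stride=4)
    tau_u, tau_b = [], []
    waits_u, waits_b = [], []
    for i in range(n_pairs):
        res = transition_times(ens.times, ens.positions[:, i, 0],
                               threshold=0.0, dwell_time=dwell)
        if res.n_events == 0:
            tau_u.append(float(ens.times[-1]))
            waits_u.append(np.array([ens.times[-1]]))
        else:
            tau_u.append(res.tau)
            waits_u.append(np.diff(np.concatenate([[ens.times[0]],
                                                   res.crossing_times])))
        s = _child_seed(seed, 100 + i)
        tb, wb = _escape_run(s, True, steps_biased, a, friction, dwell)
        tau_b.append(tb)
        waits_b.append(wb)
    tau_u = np.asarray(tau_u)
    tau_b = np.asarray(tau_b)
    rho = tau_u / tau_b
    pooled_u = np.concatenate(waits_u)
    pooled_b = np.concatenate(waits_b)
    mw = stats.mannwhitneyu(pooled_b, pooled_u, alternative="less")
    return AccelerationStudy(
        tau_unbiased=tau_u,
        tau_biased=tau_b,
        rho_per_pair=rho,
        rho_pooled=float(tau_u.mean() / tau_b.mean()),
        fraction_rho_ge_1=float(np.mean(rho >= 1.0)),
        mannwhitney_p=float(mw.pvalue),
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# restraint steering on the bead chain
# ---------------------------------------------------------------------------

@dataclass
class SteeringStudy:
    delta_restrained: np.ndarray  # per-seed mean Delta over the last quarter
    delta_unrestrained: np.ndarray
    reduction: float
    reduction_se: float
    reduction_se_units: float
    max_restrained_excess: float
    n_seeds: int


def steering_bead_chain(seed: int = 0, n_seeds: int = 20,
                        n_steps: int = 15_000, n_beads: int = 10,
                        d0: float = 0.75) -> SteeringStudy:
    """Restrained vs unrestrained biased runs of the bead chain.

    One crosslink-style restraint spans the chain ends (straight-chain
    distance (n_beads-1) * 0.25 nm, target d0); the cosine-reweighted
    bias should steer the restrained runs toward Delta = d - d0 = 0 while
    the unrestrained bias has no preferred direction.  Also tracks the
    per-step contract |restrained bias| <= |bias| (max excess over all
    steps and runs; must be <= 0 up to round-off).
    """
    record = RestraintRecord(0, [0], [n_beads - 1], d0)
    d_rest, d_unrest = [], []
    excess = 0.0
    for i in range(n_seeds):
        s = _child_seed(seed, 500 + i)
        means = []
        for use_restraint in (True, False):
            cfg = resolve_config({
                "seed": s,
                "system": {"name": "bead_chain", "n": n_beads},
            })
            system, integ, bias, _ = build_run(cfg)
            traj = run_trajectory(
                system, integ, bias_stack=bias,
                restraints=[record] if use_restraint else None,
                n_steps=n_steps, stride=10,
            )
            rep = fulfillment_report(traj, [record])
            last = rep.delta[3 * rep.delta.shape[0] // 4:, 0]
            means.append(float(last.mean()))
            if use_restraint:
                excess = max(excess, bias.max_restrained_excess)
        d_rest.append(means[0])
        d_unrest.append(means[1])
    d_rest = np.asarray(d_rest)
    d_unrest = np.asarray(d_unrest)
    diff = d_unrest - d_rest
    red_se = float(diff.std(ddof=1) / np.sqrt(n_seeds))
    return SteeringStudy(
        delta_restrained=d_rest,
        delta_unrestrained=d_unrest,
        reduction=float(diff.mean()),
        reduction_se=red_se,
        reduction_se_units=float(diff.mean() / red_se) if red_se > 0 else np.inf,
        max_restrained_excess=float(excess),
        n_seeds=n_seeds,
    )
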