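"""Stochastic dynamics engine.

A minimal Langevin integrator (BAOAB splitting) over the built-in model
systems.  The engine itself knows nothing about biasing: every step it
accepts an externally supplied *extra gradient* that is simply added to
the system gradient, so the entire hybrid-Hamiltonian machinery lives
outside it.  With the extra gradient identically zero the engine is plain
Langevin dynamics, and that limit is an exact (bit-level) contract.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathmd.units import KB
from pathmd.rng import all_streams


@dataclass
class SystemState:
    """Positions (nm), momenta (amu·nm/ps) and time (ps)."""

    q: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.q.shape != self.p.shape:
            raise ValueError("q and p must have the same shape")

    def copy(self) -> "SystemState":
        return SystemState(self.q.copy(), self.p.copy(), self.t)


@dataclass
class IntegratorConfig:
    """Timestep (ps), bath temperature (K), friction (1/ps), master seed."""

    dt: float = 0.005
    temperature: float = 300.0
    friction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


def instantaneous_temperature(state: SystemState, masses: np.ndarray) -> float:
    """Kinetic temperature 2*KE / (dof * kB) in kelvin."""
    p = np.asarray(state.p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite momenta")
    dof = p.size
    if dof == 0:
        raise ValueError("zero degrees of freedom")
    m = np.broadcast_to(np.asarray(masses, dtype=float)[:, None], p.shape)
    ke = 0.5 * np.sum(p**2 / m)
    return float(2.0 * ke / (dof * KB))


def _baoab(state, system, extra_gradient, config, rng, grad=None, m=None, c2=None):
    """One BAOAB step; returns (new_state, gradient_at_new_q).

    The extra gradient is held constant across the step (it is
    re-evaluated once per step by the caller), while the system gradient
    is refreshed for the final kick.  ``m`` and ``c2`` may be passed in
    precomputed (they depend only on masses, dt, friction and T); the
    arithmetic is identical either way.
    """
    dt = config.dt
    if m is None:
        m = np.broadcast_to(system.masses[:, None], state.q.shape)
    if grad is None:
        grad = system.gradient(state.q)
    force = -(grad + extra_gradient)
    # sum-based check: any nan/inf in the force makes the sum non-finite
    if not math.isfinite(float(force.sum())):
        raise FloatingPointError(
            f"non-finite force at t={state.t} (max |grad|="
            f"{np.max(np.abs(grad)):.3g}, max |extra|="
            f"{np.max(np.abs(extra_gradient)):.3g})"
        )
    c1 = np.exp(-config.friction * dt)
    if c2 is None:
        c2 = np.sqrt((1.0 - c1 * c1) * m * KB * config.temperature)
    p = state.p + 0.5 * dt * force
    q = state.q + 0.5 * dt * p / m
    # the noise draw happens unconditionally so the thermostat stream is
    # consumed identically for every configuration with the same seed
    p = c1 * p + c2 * rng.standard_normal(p.shape)
    q = q + 0.5 * dt * p / m
    if getattr(system, "periodic", False):
        period = getattr(system, "period", 2.0 * np.pi)
        q = (q + 0.5 * period) % period - 0.5 * period
    grad_new = system.gradient(q)
    force_new = -(grad_new + extra_gradient)
    if not math.isfinite(float(force_new.sum())):
        raise FloatingPointError(f"non-finite force after drift at t={state.t}")
    p = p + 0.5 * dt * force_new
    return SystemState(q, p, state.t + dt), grad_new


def langevin_step(state, system, extra_gradient, config, rng) -> SystemState:
    """Advance one step of BAOAB Langevin dynamics.

    ``extra_gradient`` (same shape as ``q``) is added to the system
    gradient; the applied force is -(grad_system + extra_gradient).
    Deterministic given the generator state and inputs.
    """
    extra_gradient = np.asarray(extra_gradient, dtype=float)
    if extra_gradient.shape != state.q.shape:
        raise ValueError("extra_gradient shape must match q")
    new_state, _ = _baoab(state, system, extra_gradient, config, rng)
    return new_state


@dataclass
class TrajectoryRecord:
    """Strided trajectory samples plus per-step bias diagnostics."""

    times: np.ndarray
    positions: np.ndarray  # (frames, n_particles, dim)
    momenta: np.ndarray
    potential: np.ndarray  # unbiased V(A) only; the bias never enters it
    kinetic: np.ndarray
    alpha_md: np.ndarray
    alpha_prime: np.ndarray
    bias_norm_ab: np.ndarray
    bias_norm_sigma: np.ndarray
    restraint_distances: np.ndarray | None = None  # (frames, n_restraints)
    dt: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        f, n, d = self.positions.shape
        cols = {"t": self.times}
        for k in range(n):
            for a in range(d):
                cols[f"q_{k}_{a}"] = self.positions[:, k, a]
        for k in range(n):
            for a in range(d):
                cols[f"p_{k}_{a}"] = self.momenta[:, k, a]
        cols["V"] = self.potential
        cols["KE"] = self.kinetic
        cols["alpha_md"] = self.alpha_md
        cols["alpha_prime"] = self.alpha_prime
        cols["bias_norm_ab"] = self.bias_norm_ab
        cols["bias_norm_sigma"] = self.bias_norm_sigma
        if self.restraint_distances is not None:
            for r in range(self.restraint_distances.shape[1]):
                cols[f"d_r{r}"] = self.restraint_distances[:, r]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    def write_xyz(self, path, element: str = "C") -> None:
        """Standard XYZ output for 3-dimensional systems (coordinates in
        angstrom, i.e. nm × 10)."""
        if self.positions.shape[2] != 3:
            raise ValueError("XYZ output requires a 3-dimensional system")
        buf = io.StringIO()
        n = self.positions.shape[1]
        for fi in range(self.n_frames):
            buf.write(f"{n}\n")
            buf.write(f"t= {self.times[fi]:.6f} ps\n")
            for k in range(n):
                x, y, z = self.positions[fi, k] * 10.0
                buf.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def run_trajectory(
    system,
    config: IntegratorConfig,
    bias_stack=None,
    restraints=None,
    n_steps: int = 0,
    stride: int = 1,
    initial_state: SystemState | None = None,
    rngs: dict | None = None,
) -> TrajectoryRecord:
    """Integrate ``n_steps`` of (possibly biased) Langevin dynamics.

    Per step: integrate with the extra gradient frozen from the previous
    step's bias evaluation, then feed the displacement to the bias stack
    (path accumulators, window closures, hill deposits, renormalization,
    restraint overlap) to produce the next step's extra gradient.  With
    ``bias_stack=None`` the loop is bit-identical to repeatedly calling
    :func:`langevin_step` with a zero extra gradient.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if bias_stack is not None:
        bias_stack.validate(config)
    if rngs is None:
        rngs = all_streams(config.seed)
    if initial_state is None:
        q0 = system.initial_coordinates()
        initial_state = SystemState(q0, np.zeros_like(q0), 0.0)
    state = initial_state.copy()

    n_frames = n_steps // stride + 1
    shape = state.q.shape
    times = np.empty(n_frames)
    positions = np.empty((n_frames,) + shape)
    momenta = np.empty((n_frames,) + shape)
    potential = np.empty(n_frames)
    kinetic = np.empty(n_frames)
    a_md = np.zeros(n_frames)
    a_pr = np.zeros(n_frames)
    nrm_ab = np.zeros(n_frames)
    nrm_sg = np.zeros(n_frames)
    dists = None
    if restraints:
        from pathmd.restraints_io import effective_distance

        dists = np.empty((n_frames, len(restraints)))

    m2 = np.broadcast_to(system.masses[:, None], shape)

    def record(fi, diag):
        times[fi] = state.t
        positions[fi] = state.q
        momenta[fi] = state.p
        potential[fi] = system.energy(state.q)
        kinetic[fi] = 0.5 * np.sum(state.p**2 / m2)
        a_md[fi] = diag.get("alpha_md", 0.0)
        a_pr[fi] = diag.get("alpha_prime", 0.0)
        nrm_ab[fi] = diag.get("bias_norm_ab", 0.0)
        nrm_sg[fi] = diag.get("bias_norm_sigma", 0.0)
        if dists is not None:
            for r, rec in enumerate(restraints):
                dists[fi, r] = effective_distance(state.q, rec)[0]

    diag = {}
    record(0, diag)
    extra = np.zeros(shape)
    grad = system.gradient(state.q)
    c1 = np.exp(-config.friction * config.dt)
    c2 = np.sqrt((1.0 - c1 * c1) * m2 * KB * config.temperature)
    thermostat = rngs["thermostat"]
    fi = 1
    for step in range(1, n_steps + 1):
        prev = state
        state, grad = _baoab(prev, system, extra, config, thermostat, grad, m2, c2)
        if bias_stack is not None:
            extra, diag = bias_stack.step(
                prev, state, grad, system, restraints, rngs
            )
        if step % stride == 0:
            record(fi, diag)
            fi += 1
    return TrajectoryRecord(
        times=times,
        positions=positions,
        momenta=momenta,
        potential=potential,
        kinetic=kinetic,
        alpha_md=a_md,
        alpha_prime=a_pr,
        bias_norm_ab=nrm_ab,
        bias_norm_sigma=nrm_sg,
        restraint_distances=dists,
        dt=config.dt,
    )
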