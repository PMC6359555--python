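"""Action-path increments and the adaptive-bias component.

Each integrator step contributes a per-atom increment
dL = (p + dp) ∘ dq (elementwise product, momenta times displacement)
to a running action-path variable L_ik, tracked independently for each
of N_R parallel biases i and each atom k.  The adaptive-bias gradient for
ladder rung i is re-evaluated whenever its window tau1_i = i*tau1 closes:
the window-accumulated increment vector, divided by the window length and
scaled by a constant fluctuation amplitude gamma'' and a fresh
standard-normal draw zeta, is frozen and applied as a gradient until the
next closure.  Because zeta has zero mean, the bias averages to zero over
many windows and acts as a slowly varying random tilt whose direction is
informed by the recent path history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BiasSchedule:
    """Ladders of window lengths tau1_i = i*tau1, tau2_i = i*tau2.

    Periods are converted to whole step counts by rounding to the nearest
    step (minimum one step).
    """

    n_r: int
    tau1: float
    tau2: float
    dt: float
    tau1_ladder: np.ndarray = field(init=False)
    tau2_ladder: np.ndarray = field(init=False)
    steps1: np.ndarray = field(init=False)
    steps2: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.n_r < 1:
            raise ValueError("n_r must be >= 1")
        if self.tau1 < self.dt or self.tau2 < self.dt:
            raise ValueError("bias periods tau1, tau2 must be >= dt")
        i = np.arange(1, self.n_r + 1)
        self.tau1_ladder = i * float(self.tau1)
        self.tau2_ladder = i * float(self.tau2)
        self.steps1 = np.maximum(1, np.rint(self.tau1_ladder / self.dt)).astype(int)
        self.steps2 = np.maximum(1, np.rint(self.tau2_ladder / self.dt)).astype(int)


def build_bias_schedule(n_r: int, tau1: float, tau2: float, dt: float) -> BiasSchedule:
    """Build the ladder schedule (see :class:`BiasSchedule`)."""
    return BiasSchedule(n_r=n_r, tau1=tau1, tau2=tau2, dt=dt)


def accumulate_dL(prev, curr, periodic: bool = False, period: float = 2.0 * np.pi):
    """Per-step path increment between two consecutive states.

    Returns ``(vector_increment, scalar_increment)`` where the vector
    increment is (p + dp) ∘ dq per component and the scalar increment is
    its per-atom sum, with dq = q_curr - q_prev (minimum image for
    periodic coordinates), dp = p_curr - p_prev and p = p_prev.
    """
    if prev.q.shape != curr.q.shape:
        raise ValueError("mismatched state shapes")
    dq = curr.q - prev.q
    if periodic:
        dq = (dq + 0.5 * period) % period - 0.5 * period
    dp = curr.p - prev.p
    vec = (prev.p + dp) * dq
    return vec, vec.sum(axis=-1)


@dataclass
class PathAccumulator:
    """Window accumulators and frozen adaptive-bias gradients.

    ``window_vec[i]`` collects the elementwise increments over the
    currently open tau1_i window; ``L`` is the running (never reset)
    scalar path variable per (bias, atom); ``frozen[i]`` is the gradient
    applied during the current window for ladder rung i.
    """

    schedule: BiasSchedule
    n_atoms: int
    dim: int
    gamma_pp: float = 1e-4

    def __post_init__(self):
        nr = self.schedule.n_r
        self.window_vec = np.zeros((nr, self.n_atoms, self.dim))
        self.L = np.zeros((nr, self.n_atoms))
        self.frozen = np.zeros((nr, self.n_atoms, self.dim))
        self.step_count = 0
        self.window_start = np.zeros(nr, dtype=int)

    def update(self, vec_increment: np.ndarray, scalar_increment: np.ndarray) -> None:
        """Feed one step's increments into every open window."""
        if vec_increment.shape != (self.n_atoms, self.dim):
            raise ValueError("vector increment shape mismatch")
        self.step_count += 1
        self.window_vec += vec_increment[None, :, :]
        self.L += scalar_increment[None, :]

    def due_windows(self) -> np.ndarray:
        """Ladder indices whose tau1 window closes at the current step."""
        return np.nonzero(self.step_count % self.schedule.steps1 == 0)[0]

    def close_window(self, i: int, zeta: np.ndarray) -> np.ndarray:
        """Freeze the gradient for rung ``i`` and reset its window.

        g_i,k = gamma'' * zeta_k * (window sum)_k / tau1_i.  Must be
        called exactly at a window boundary.
        """
        if self.step_count % self.schedule.steps1[i] != 0:
            raise ValueError(
                f"window {i} closed mid-window (step {self.step_count}, "
                f"period {self.schedule.steps1[i]})"
            )
        tau = self.schedule.tau1_ladder[i]
        self.frozen[i] = self.gamma_pp * np.asarray(zeta)[:, None] * self.window_vec[i] / tau
        self.window_vec[i] = 0.0
        self.window_start[i] = self.step_count
        return self.frozen[i]

    def total_gradient(self) -> np.ndarray:
        """Adaptive-bias gradient summed over the ladder, per atom."""
        return self.frozen.sum(axis=0)


def adaptive_bias_gradient(acc: PathAccumulator, i: int, k: int, zeta: float) -> np.ndarray:
    """Single-(i,k) window closure, returning that atom's frozen gradient.

    Provided for inspection and testing; the stack closes whole rungs at
    once via :meth:`PathAccumulator.close_window`.
    """
    if acc.step_count % acc.schedule.steps1[i] != 0:
        raise ValueError("adaptive bias gradient requested mid-window")
    tau = acc.schedule.tau1_ladder[i]
    g = acc.gamma_pp * zeta * acc.window_vec[i, k] / tau
    acc.frozen[i, k] = g
    acc.window_vec[i, k] = 0.0
    return g
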