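"""Path-sampling component: sigma coordinates and Gaussian hill history.

The running path coordinate sigma_ik accumulates the scalar dL increment
every step.  At intervals tau2_i = i*tau2 a repulsive Gaussian hill of
height W and width delta_sigma is deposited at the current sigma_ik, so
revisiting previously sampled stretches of the path becomes increasingly
unfavourable.  The force the hills exert in sigma space maps back to atom
coordinates through the chain vector (p + dp), the derivative of the path
increment with respect to displacement.

The hill kernel is the conventional metadynamics Gaussian
exp(-(sigma - sigma_c)^2 / (2 delta_sigma^2)); hills are one-dimensional
and independent per (bias, atom) pair.  A well-tempered variant (hill
height damped by exp(-U_acc/delta_e)) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: hills farther than this many widths from sigma exert no force
_BAND_WIDTHS = 8.0


@dataclass
class SigmaState:
    """Current sigma values per (bias i, atom k) plus the chain vector."""

    n_r: int
    n_atoms: int
    dim: int

    def __post_init__(self):
        self.sigma = np.zeros((self.n_r, self.n_atoms))
        self.chain = np.zeros((self.n_atoms, self.dim))
        self.step_stamp = 0


def update_sigma(state: SigmaState, scalar_increment: np.ndarray,
                 chain_vectors: np.ndarray, step: int | None = None) -> SigmaState:
    """Advance sigma by one step's scalar increment; store the chain vector.

    The same per-atom scalar increment feeds every ladder rung (the rungs
    differ only in when they deposit hills), and the chain vector is the
    current (p + dp) per atom.
    """
    scalar_increment = np.asarray(scalar_increment, dtype=float)
    if scalar_increment.shape != (state.n_atoms,):
        raise ValueError("scalar increment must be per-atom")
    chain_vectors = np.asarray(chain_vectors, dtype=float)
    if chain_vectors.shape != (state.n_atoms, state.dim):
        raise ValueError("chain vector shape mismatch")
    state.sigma += scalar_increment[None, :]
    state.chain = chain_vectors
    state.step_stamp = state.step_stamp + 1 if step is None else int(step)
    return state


class GaussianHistory:
    """Deposited hill centers per ladder rung, with heights and width.

    Centers and effective heights are stored in per-rung growable arrays;
    the ``centers``/``heights`` properties expose them as lists of
    per-deposit rows.  ``delta_sigma`` may start as None ("auto"): it is
    then set at the first deposit as a fraction of the running spread of
    the sigma path over the calibration stretch, clamped to
    ``dsigma_floor``.
    """

    def __init__(self, n_r: int, n_atoms: int, w: float = 0.1,
                 delta_sigma: float | None = None, dsigma_floor: float = 1e-4,
                 delta_e: float = 1000.0, well_tempered: bool = False):
        if delta_sigma is not None and delta_sigma <= 0:
            raise ValueError("delta_sigma must be positive")
        self.n_r = int(n_r)
        self.n_atoms = int(n_atoms)
        self.w = float(w)
        self.delta_sigma = delta_sigma
        self.dsigma_floor = float(dsigma_floor)
        self.delta_e = float(delta_e)
        self.well_tempered = bool(well_tempered)
        self._n = [0] * self.n_r
        self._c = [np.empty((8, self.n_atoms)) for _ in range(self.n_r)]
        self._h = [np.empty((8, self.n_atoms)) for _ in range(self.n_r)]
        self.deposit_steps: list[list[int]] = [[] for _ in range(self.n_r)]
        self._sigma_samples: list[np.ndarray] = []
        # all-rung flattened storage for the summed-force fast path
        self._fn = 0
        self._fc = np.empty((16, self.n_atoms))
        self._fh = np.empty((16, self.n_atoms))

    # -- storage views -----------------------------------------------------
    @property
    def centers(self) -> list[list[np.ndarray]]:
        return [[self._c[i][j] for j in range(self._n[i])] for i in range(self.n_r)]

    @property
    def heights(self) -> list[list[np.ndarray]]:
        return [[self._h[i][j] for j in range(self._n[i])] for i in range(self.n_r)]

    def n_hills(self, i: int) -> int:
        return self._n[i]

    # -- width calibration -------------------------------------------------
    def observe_sigma(self, sigma_row: np.ndarray) -> None:
        """Collect per-atom sigma values until the width is calibrated."""
        if self.delta_sigma is None:
            self._sigma_samples.append(np.asarray(sigma_row, dtype=float).copy())

    def ensure_width(self) -> float:
        """Calibrate delta_sigma = max(0.5 * std of the observed sigma
        path, floor) at the first deposit; a no-op afterwards."""
        if self.delta_sigma is None:
            if self._sigma_samples:
                spread = float(np.std(np.concatenate(self._sigma_samples)))
            else:
                spread = 0.0
            self.delta_sigma = max(0.5 * spread, self.dsigma_floor)
            self._sigma_samples = []
        return self.delta_sigma

    # -- deposits ----------------------------------------------------------
    def deposit(self, i: int, sigma_i: np.ndarray, step: int) -> None:
        """Append one hill per atom for rung ``i`` at the current sigma."""
        self.ensure_width()
        if self.well_tempered:
            u_acc = self._potential_rung(i, np.asarray(sigma_i, dtype=float))
            h = self.w * np.exp(-u_acc / self.delta_e)
        else:
            h = np.full(self.n_atoms, self.w)
        n = self._n[i]
        if n == self._c[i].shape[0]:
            self._c[i] = np.concatenate([self._c[i], np.empty_like(self._c[i])])
            self._h[i] = np.concatenate([self._h[i], np.empty_like(self._h[i])])
        self._c[i][n] = sigma_i
        self._h[i][n] = h
        self._n[i] = n + 1
        self.deposit_steps[i].append(int(step))
        if self._fn == self._fc.shape[0]:
            self._fc = np.concatenate([self._fc, np.empty_like(self._fc)])
            self._fh = np.concatenate([self._fh, np.empty_like(self._fh)])
        self._fc[self._fn] = sigma_i
        self._fh[self._fn] = h
        self._fn += 1

    def _potential_rung(self, i: int, sigma_i: np.ndarray) -> np.ndarray:
        n = self._n[i]
        if n == 0:
            return np.zeros(self.n_atoms)
        d = sigma_i[None, :] - self._c[i][:n]
        return np.sum(
            self._h[i][:n] * np.exp(-(d**2) / (2.0 * self.delta_sigma**2)), axis=0
        )

    def potential(self, sigma: np.ndarray) -> np.ndarray:
        """Accumulated hill potential U(sigma), shape (n_r, n_atoms)."""
        out = np.zeros((self.n_r, self.n_atoms))
        if self.delta_sigma is None:
            return out
        for i in range(self.n_r):
            if self._n[i]:
                out[i] = self._potential_rung(i, np.asarray(sigma[i], dtype=float))
        return out

    def phi(self, sigma: np.ndarray) -> np.ndarray:
        """Repulsive hill force Phi = -dU/dsigma, shape (n_r, n_atoms).

        Hills farther than a few widths from the current sigma are
        skipped before any exponential is evaluated.
        """
        out = np.zeros((self.n_r, self.n_atoms))
        if self.delta_sigma is None:
            return out
        ds2 = self.delta_sigma**2
        band = _BAND_WIDTHS * self.delta_sigma
        for i in range(self.n_r):
            n = self._n[i]
            if n == 0:
                continue
            d = sigma[i][None, :] - self._c[i][:n]
            near = np.abs(d) < band
            if not near.any():
                continue
            contrib = np.zeros_like(d)
            dn = d[near]
            contrib[near] = (
                self._h[i][:n][near] * (dn / ds2) * np.exp(-(dn**2) / (2.0 * ds2))
            )
            out[i] = contrib.sum(axis=0)
        return out

    def phi_sum(self, sigma_row: np.ndarray) -> np.ndarray:
        """Hill force summed over all rungs at a shared sigma row.

        Equivalent to ``phi(sigma).sum(axis=0)`` when every rung carries
        the same sigma values (always true when all rungs start from the
        same origin and receive the same increments), but evaluated in a
        single pass over the flattened hill store.
        """
        if self.delta_sigma is None or self._fn == 0:
            return np.zeros(self.n_atoms)
        ds2 = self.delta_sigma**2
        d = sigma_row[None, :] - self._fc[: self._fn]
        near = np.abs(d) < _BAND_WIDTHS * self.delta_sigma
        if not near.any():
            return np.zeros(self.n_atoms)
        contrib = np.zeros_like(d)
        dn = d[near]
        contrib[near] = (
            self._fh[: self._fn][near] * (dn / ds2) * np.exp(-(dn**2) / (2.0 * ds2))
        )
        return contrib.sum(axis=0)


def deposit_hill(history: GaussianHistory, sigma_state: SigmaState,
                 step: int, schedule) -> GaussianHistory:
    """Deposit hills for every ladder rung due at ``step``.

    Rejects off-boundary calls: ``step`` must be a tau2 boundary for at
    least one rung, and only due rungs receive a hill.
    """
    due = np.nonzero(step % schedule.steps2 == 0)[0]
    if len(due) == 0:
        raise ValueError(f"step {step} is not a tau2 boundary for any rung")
    for i in due:
        history.deposit(int(i), sigma_state.sigma[i], step)
    return history


def hill_force(history: GaussianHistory, sigma_value: float, i: int, k: int) -> float:
    """Force in sigma space on coordinate (i, k) at ``sigma_value``.

    Phi = W * sum_c (sigma - sigma_c)/delta^2 * exp(-(sigma-sigma_c)^2/(2 delta^2)),
    i.e. minus the derivative of the accumulated Gaussian potential:
    positive above a hill center, pushing sigma away from it.
    """
    if history.n_hills(i) == 0:
        return 0.0
    if history.delta_sigma is None:
        raise ValueError("hill width not calibrated")
    if history.delta_sigma <= 0:
        raise ValueError("delta_sigma must be positive")
    n = history._n[i]
    c = history._c[i][:n, k]
    h = history._h[i][:n, k]
    ds2 = history.delta_sigma**2
    d = sigma_value - c
    return float(np.sum(h * (d / ds2) * np.exp(-(d**2) / (2.0 * ds2))))


def sigma_chain_rule(phi: np.ndarray, chain_vectors: np.ndarray,
                     phi_stamp: int | None = None,
                     chain_stamp: int | None = None) -> np.ndarray:
    """Map hill forces back to atoms: out_k = sum_i Phi_ik * chain_k.

    The result is the repulsive force direction in atom space (the bias
    stack inserts it into the gradient bundle with the appropriate sign).
    Raises if the chain vectors are stale relative to the hill forces.
    """
    if phi_stamp is not None and chain_stamp is not None and phi_stamp != chain_stamp:
        raise ValueError("stale chain vectors: time stamps differ")
    phi = np.asarray(phi, dtype=float)
    chain = np.asarray(chain_vectors, dtype=float)
    if phi.shape[1] != chain.shape[0]:
        raise ValueError("phi and chain vector atom counts differ")
    return phi.sum(axis=0)[:, None] * chain
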