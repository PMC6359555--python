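import numpy as np
import pytest

from pathmd.engine import SystemState


def central_difference_gradient(energy_fn, q, h=1e-5):
    """Independent finite-difference oracle for analytic gradients."""
    q = np.asarray(q, dtype=float)
    grad = np.zeros_like(q)
    flat = q.ravel()
    g = grad.ravel()
    for i in range(flat.size):
        qp = flat.copy()
        qm = flat.copy()
        qp[i] += h
        qm[i] -= h
        g[i] = (energy_fn(qp.reshape(q.shape)) - energy_fn(qm.reshape(q.shape))) / (2 * h)
    return grad


class ZeroPotential:
    """Free particle(s): V = 0 everywhere."""

    def __init__(self, n_particles=1, dimension=1, mass=1.0):
        self.n_particles = n_particles
        self.dimension = dimension
        self.masses = np.full(n_particles, float(mass))
        self.periodic = False

    def energy(self, q):
        return 0.0

    def gradient(self, q):
        return np.zeros_like(np.asarray(q, dtype=float))

    def energy_gradient(self, q):
        return 0.0, self.gradient(q)

    def initial_coordinates(self):
        return np.zeros((self.n_particles, self.dimension))


class HarmonicWell:
    """V = 1/2 k |q|^2 per particle."""

    def __init__(self, k=100.0, n_particles=1, dimension=1, mass=1.0):
        self.k = k
        self.n_particles = n_particles
        self.dimension = dimension
        self.masses = np.full(n_particles, float(mass))
        self.periodic = False

    def energy(self, q):
        q = np.asarray(q, dtype=float)
        return float(0.5 * self.k * np.sum(q * q))

    def gradient(self, q):
        return self.k * np.asarray(q, dtype=float)

    def energy_gradient(self, q):
        return self.energy(q), self.gradient(q)

    def initial_coordinates(self):
        return np.zeros((self.n_particles, self.dimension))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state_pair(rng, n=3, dim=3, scale=0.1):
    """Two states one notional step apart, for increment oracles."""
    q0 = rng.normal(size=(n, dim))
    p0 = rng.normal(size=(n, dim))
    prev = SystemState(q0, p0, 0.0)
    curr = SystemState(q0 + scale * rng.normal(size=(n, dim)),
                       p0 + scale * rng.normal(size=(n, dim)), 0.001)
    return prev, curr
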