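"""Built-in analytic model systems and restraint-fixture generation.

Every system exposes the same small surface: ``energy(q)`` and
``gradient(q)`` on coordinates of shape ``(n_particles, dimension)``,
per-particle ``masses`` (amu), per-coordinate periodicity, and a
deterministic ``initial_coordinates()``.  The systems are deliberately
tiny — a quartic double well (one or two coordinates per particle), the
Müller–Brown surface, a periodic three-basin torsional surface, and a
restrainable bead chain with harmonic bonds and a purely repulsive
nonbonded term — so that the biasing machinery can be exercised and
validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


def _check_finite(q: np.ndarray, what: str = "coordinates") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    # a non-finite entry makes the sum non-finite (inf - inf gives nan)
    if not np.isfinite(np.sum(q)):
        raise ValueError(f"non-finite {what}")
    return q


def double_well_potential(q, a: float, b: float):
    """Quartic double well, summed per coordinate.

    V(x) = a ((x/b)^2 - 1)^2 for each coordinate x, so the minima sit at
    x = ±b with V = 0 and the barrier top at x = 0 with V = a.

    Returns ``(energy, gradient)`` with the gradient of the same shape
    as ``q``.
    """
    if not (a > 0 and b > 0):
        raise ValueError("double well requires a > 0 and b > 0")
    q = _check_finite(q)
    u = (q / b) ** 2 - 1.0
    energy = float((a * u * u).sum())
    grad = 4.0 * a * u * q / b**2
    return energy, grad


def torsion_surface_potential(angles, a: float = 6.0, b: float = 4.0):
    """Periodic three-basin surface on two torsional coordinates.

    V(phi, psi) = a (1 - cos 3 phi) + b (1 - cos psi): three equivalent
    basins at phi in {0, ±2pi/3} (barrier 2a between them) times a single
    psi basin at 0 (barrier 2b), both coordinates 2pi-periodic.  A
    surrogate for a dipeptide backbone landscape at the level needed to
    test periodic path accumulation.
    """
    ang = _check_finite(np.asarray(angles, dtype=float), "angles")
    phi = ang[..., 0]
    psi = ang[..., 1]
    energy = float(np.sum(a * (1.0 - np.cos(3.0 * phi)) + b * (1.0 - np.cos(psi))))
    grad = np.empty_like(ang)
    grad[..., 0] = 3.0 * a * np.sin(3.0 * phi)
    grad[..., 1] = b * np.sin(psi)
    return energy, grad


# Müller–Brown constants (energies read as kJ/mol, lengths as nm).
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown_potential(q, scale: float = 0.1):
    """Müller–Brown two-dimensional surface (optionally rescaled).

    The classical four-Gaussian test surface; ``scale`` multiplies the
    conventional constants so the barrier heights land in a range a
    thermal trajectory at a few hundred kelvin can cross.
    """
    q = _check_finite(q)
    x = q[..., 0, None]
    y = q[..., 1, None]
    dx = x - _MB_x0
    dy = y - _MB_y0
    e = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    energy = float(scale * np.sum(e))
    gx = np.sum(e * (2.0 * _MB_a * dx + _MB_b * dy), axis=-1)
    gy = np.sum(e * (_MB_b * dx + 2.0 * _MB_c * dy), axis=-1)
    grad = scale * np.stack([gx, gy], axis=-1)
    return energy, grad


@dataclass
class ToySystem:
    """A separable analytic surface evaluated per particle.

    ``potential_id`` selects the analytic form; coordinates have shape
    ``(n_particles, dimension)``.  For multi-particle instances the
    particles are independent copies of the same surface (useful for
    vectorized ensembles of walkers).
    """

    n_particles: int
    dimension: int
    masses: np.ndarray
    potential_id: str
    parameters: dict = field(default_factory=dict)
    periodic: bool = False
    period: float = TWO_PI

    def __post_init__(self):
        self.masses = np.broadcast_to(
            np.asarray(self.masses, dtype=float), (self.n_particles,)
        ).copy()
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    # -- energy / gradient ------------------------------------------------
    def energy_gradient(self, q):
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_particles, self.dimension):
            raise ValueError(
                f"coordinate shape {q.shape} != {(self.n_particles, self.dimension)}"
            )
        if self.potential_id == "double_well":
            return double_well_potential(q, **self.parameters)
        if self.potential_id == "torsion_surface":
            return torsion_surface_potential(q, **self.parameters)
        if self.potential_id == "muller_brown":
            return muller_brown_potential(q, **self.parameters)
        raise KeyError(f"unknown potential {self.potential_id!r}")

    def energy(self, q) -> float:
        return self.energy_gradient(q)[0]

    def gradient(self, q) -> np.ndarray:
        return self.energy_gradient(q)[1]

    def initial_coordinates(self) -> np.ndarray:
        q = np.zeros((self.n_particles, self.dimension))
        if self.potential_id == "double_well":
            q[:] = -self.parameters.get("b", 0.5)
        elif self.potential_id == "muller_brown":
            q[:] = (-0.558, 1.442)  # deepest basin
        # torsion surface: basin at the origin already
        return q


@dataclass
class BeadChain:
    """Linear bead chain: harmonic bonds + truncated repulsive nonbonded.

    The nonbonded term is the purely repulsive Weeks–Chandler–Andersen
    form (Lennard-Jones shifted up by eps and cut at 2^(1/6) sigma),
    applied to all pairs except directly bonded neighbours, so compaction
    is never driven by the force field itself — only by restraints or
    bias.
    """

    n_beads: int
    bond_k: float = 250.0  # kJ/mol/nm^2
    bond_r0: float = 0.25  # nm
    repulsion_eps: float = 1.0  # kJ/mol
    repulsion_sigma: float = 0.3  # nm
    mass: float = 10.0  # amu per bead

    periodic: bool = False

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("a chain needs at least 2 beads")
        self.n_particles = self.n_beads
        self.dimension = 3
        self.masses = np.full(self.n_beads, float(self.mass))
        self._rc = 2.0 ** (1.0 / 6.0) * self.repulsion_sigma
        self._pairs = np.triu_indices(self.n_beads, k=2)

    def initial_coordinates(self) -> np.ndarray:
        q = np.zeros((self.n_beads, 3))
        q[:, 0] = self.bond_r0 * np.arange(self.n_beads)
        return q

    def bond_energy(self, q) -> float:
        d = np.linalg.norm(np.diff(q, axis=0), axis=1)
        return float(0.5 * self.bond_k * np.sum((d - self.bond_r0) ** 2))

    def repulsion_energy(self, q) -> float:
        return self._nonbonded(np.asarray(q, dtype=float))[0]

    def _nonbonded(self, q):
        i, j = self._pairs  # all pairs except bonded neighbours
        rij = q[i] - q[j]
        d = np.sqrt((rij * rij).sum(axis=1))
        if np.any(d == 0.0):
            raise FloatingPointError("coincident beads in nonbonded term")
        mask = d < self._rc
        energy = 0.0
        grad = np.zeros_like(q)
        if np.any(mask):
            dm = d[mask]
            sr6 = (self.repulsion_sigma / dm) ** 6
            energy = float(
                np.sum(4.0 * self.repulsion_eps * (sr6**2 - sr6) + self.repulsion_eps)
            )
            # dV/dd = 4 eps (-12 sr12 + 6 sr6)/d
            dv = 4.0 * self.repulsion_eps * (-12.0 * sr6**2 + 6.0 * sr6) / dm
            gvec = (dv / dm)[:, None] * rij[mask]
            np.add.at(grad, i[mask], gvec)
            np.add.at(grad, j[mask], -gvec)
        return energy, grad

    def energy_gradient(self, q):
        q = _check_finite(np.asarray(q, dtype=float))
        if q.shape != (self.n_beads, 3):
            raise ValueError(f"coordinate shape {q.shape} != {(self.n_beads, 3)}")
        bond_vec = np.diff(q, axis=0)
        d = np.linalg.norm(bond_vec, axis=1)
        if np.any(d == 0.0):
            raise FloatingPointError("zero-length bond")
        stretch = d - self.bond_r0
        e_bond = float(0.5 * self.bond_k * np.sum(stretch**2))
        f = (self.bond_k * stretch / d)[:, None] * bond_vec  # dV/dq along bond
        grad = np.zeros_like(q)
        grad[1:] += f
        grad[:-1] -= f
        e_rep, g_rep = self._nonbonded(q)
        return e_bond + e_rep, grad + g_rep

    def energy(self, q) -> float:
        return self.energy_gradient(q)[0]

    def gradient(self, q) -> np.ndarray:
        return self.energy_gradient(q)[1]


def make_bead_chain(
    n: int,
    bond_k: float = 250.0,
    bond_r0: float = 0.25,
    repulsion_eps: float = 1.0,
    repulsion_sigma: float = 0.3,
    mass: float = 10.0,
) -> BeadChain:
    """Construct a bead chain; its initial conformation is a straight
    chain at the equilibrium bond length along x."""
    return BeadChain(
        n_beads=n,
        bond_k=bond_k,
        bond_r0=bond_r0,
        repulsion_eps=repulsion_eps,
        repulsion_sigma=repulsion_sigma,
        mass=mass,
    )


_SYSTEM_DEFAULTS = {
    "double_well_1d": dict(a=5.0, b=0.5, mass=10.0, n_particles=1),
    "double_well_2d": dict(a=5.0, b=0.5, mass=10.0, n_particles=1),
    "muller_brown": dict(scale=0.1, mass=10.0),
    "torsion_surface": dict(a=6.0, b=4.0, mass=10.0),
    "bead_chain": dict(
        n=30, bond_k=250.0, bond_r0=0.25, repulsion_eps=1.0, repulsion_sigma=0.3,
        mass=10.0,
    ),
}


def make_system(name: str, **overrides):
    """Factory for the named built-in systems.

    Names: ``double_well_1d``, ``double_well_2d``, ``muller_brown``,
    ``torsion_surface``, ``bead_chain``.  ``n_particles`` on the double
    wells instantiates independent copies (an ensemble of walkers).
    """
    if name not in _SYSTEM_DEFAULTS:
        raise KeyError(f"unknown system {name!r}; known: {sorted(_SYSTEM_DEFAULTS)}")
    params = dict(_SYSTEM_DEFAULTS[name])
    params.update(overrides)
    mass = params.pop("mass")
    if name == "bead_chain":
        return make_bead_chain(mass=mass, **params)
    if name in ("double_well_1d", "double_well_2d"):
        npart = int(params.pop("n_particles"))
        dim = 1 if name.endswith("1d") else 2
        return ToySystem(
            n_particles=npart, dimension=dim, masses=mass,
            potential_id="double_well", parameters=params,
        )
    if name == "muller_brown":
        return ToySystem(
            n_particles=1, dimension=2, masses=mass,
            potential_id="muller_brown", parameters=params,
        )
    return ToySystem(
        n_particles=1, dimension=2, masses=mass,
        potential_id="torsion_surface", parameters=params,
        periodic=True, period=TWO_PI,
    )


@dataclass
class RestraintFixture:
    """Synthetic restraint table plus its generating metadata."""

    records: list
    seed: int
    system_name: str
    note: str = "synthetic fixture; emulates an experimental crosslink table"


def generate_restraint_fixture(
    system: BeadChain,
    n_restraints: int,
    d0: float = 0.75,
    group1_size: int = 1,
    seed: int = 0,
    kind: str = "xlink",
) -> RestraintFixture:
    """Draw a deterministic synthetic restraint table on a bead chain.

    Pairs are chosen (without replacement) among bead pairs separated by
    at least 3 bonds, mirroring inter-residue crosslinks: group 1 holds
    ``group1_size`` consecutive beads around the first index (a residue's
    atoms), group 2 exactly one bead.
    """
    if n_restraints < 1:
        raise ValueError("n_restraints must be >= 1")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    n = system.n_beads
    pairs = [(i, j) for i in range(n) for j in range(i + 3, n)]
    if n_restraints > len(pairs):
        raise ValueError(
            f"{n_restraints} restraints requested but only {len(pairs)} "
            "admissible pairs (>=3 bonds apart)"
        )
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=int(seed), spawn_key=(3,)))
    )
    chosen = rng.choice(len(pairs), size=n_restraints, replace=False)
    from pathmd.restraints_io import RestraintRecord

    records = []
    for rid, idx in enumerate(sorted(int(c) for c in chosen)):
        i, j = pairs[idx]
        half = group1_size // 2
        lo = int(np.clip(i - half, 0, n - group1_size))
        group1 = list(range(lo, lo + group1_size))
        if j in group1:  # keep groups disjoint
            group1 = [g for g in group1 if g != j]
        records.append(
            RestraintRecord(id=rid, group1=group1, group2=[j], d0=float(d0), kind=kind)
        )
    return RestraintFixture(records=records, seed=int(seed), system_name="bead_chain")
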