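"""Renormalized combination of unbiased and bias gradients.

The total applied gradient is

    grad_total = grad_A (1 + alpha_md)
               + grad_ab   * alpha' |grad_A| / |grad_ab|
               + grad_sigma* alpha' |grad_A| / |grad_sigma|

so each bias component is rescaled to a fixed fraction alpha' of the
unbiased gradient norm, with alpha_md = eta_md beta_md (1 - xi) and
alpha' = eta' beta' (1 - xi') drawn fresh each step from independent
uniforms.  Optionally the bias direction per atom is replaced by the
slowest principal component of its recent history, and near restrained
atoms the bias is reweighted by the cosine overlap with the restraint
vector q12, signed by d12 - d0: treating the bias as a gradient, the
reweighted force component along the restraint always points toward
fulfilment, with magnitude |bias| cos^2(Xi), and vanishes exactly at
d12 = d0.  No restraint energy is ever added; the restraint acts purely
by filtering the bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from pathmd.action_bias import PathAccumulator, accumulate_dL
from pathmd.path_metadynamics import GaussianHistory, SigmaState


@dataclass
class CouplingParams:
    """Coupling magnitudes (beta) and fluctuation ranges (eta).

    The defaults are the magnitudes appropriate for macromolecular force
    fields, where the global gradient norm is dominated by stiff bonded
    terms; toy-system run configs override eta_prime (see the package's
    methods documentation).
    """

    beta_md: float = 1e-4
    beta_prime: float = 1e-4
    eta_md: float = 1.0
    eta_prime: float = 1.0

    def __post_init__(self):
        for name in ("beta_md", "beta_prime", "eta_md", "eta_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def draw_coupling(params: CouplingParams, rng) -> tuple[float, float]:
    """Per-step couplings (alpha_md, alpha') from two independent uniforms."""
    xi = rng.uniform()
    xi_p = rng.uniform()
    alpha_md = params.eta_md * params.beta_md * (1.0 - xi)
    alpha_p = params.eta_prime * params.beta_prime * (1.0 - xi_p)
    return alpha_md, alpha_p


@dataclass
class GradientBundle:
    """Per-atom unbiased gradient plus the two raw bias gradients."""

    grad_A: np.ndarray
    grad_ab: np.ndarray | None = None
    grad_sigma: np.ndarray | None = None

    def norm_A(self) -> float:
        return float(np.linalg.norm(self.grad_A))

    def norm_ab(self) -> float:
        return 0.0 if self.grad_ab is None else float(np.linalg.norm(self.grad_ab))

    def norm_sigma(self) -> float:
        return 0.0 if self.grad_sigma is None else float(np.linalg.norm(self.grad_sigma))


def _norm(x: np.ndarray) -> float:
    return math.sqrt(float((x * x).sum()))


def _scaled_terms(bundle: GradientBundle, alpha_prime: float,
                  per_atom: bool = False) -> dict:
    """Renormalized bias terms; zero-norm or zero-coupling terms omitted."""
    out = {}
    nA = _norm(bundle.grad_A)
    if not np.isfinite(nA):
        raise FloatingPointError("non-finite unbiased gradient norm")
    if alpha_prime == 0.0:
        return out
    nA_atom = np.sqrt(np.sum(bundle.grad_A**2, axis=-1)) if per_atom else None
    for name, B in (("ab", bundle.grad_ab), ("sigma", bundle.grad_sigma)):
        if B is None:
            continue
        if per_atom:
            nB_atom = np.sqrt(np.sum(B**2, axis=-1))
            if not np.all(np.isfinite(nB_atom)):
                raise FloatingPointError(f"non-finite {name} bias norm")
            scale = np.zeros_like(nB_atom)
            mask = nB_atom > 0
            scale[mask] = alpha_prime * nA_atom[mask] / nB_atom[mask]
            term = B * scale[:, None]
            if not term.any():
                continue
        else:
            nB = _norm(B)
            if not np.isfinite(nB):
                raise FloatingPointError(f"non-finite {name} bias norm")
            if nB == 0.0:
                continue
            term = B * (alpha_prime * nA / nB)
        out[name] = term
    return out


def combine_gradients(bundle: GradientBundle, alpha_md: float, alpha_prime: float,
                      per_atom: bool = False) -> np.ndarray:
    """Total gradient: grad_A (1+alpha_md) plus renormalized bias terms.

    With the default global norms, each included bias term has norm
    alpha' |grad_A| after rescaling; with ``per_atom=True`` the rescaling
    is applied atom by atom instead.
    """
    total = bundle.grad_A * (1.0 + alpha_md)
    for term in _scaled_terms(bundle, alpha_prime, per_atom).values():
        total = total + term
    return total


def cos_xi(bias_vec: np.ndarray, q12: np.ndarray) -> float:
    """Cosine between a bias vector and the (signed) restraint direction.

    A zero bias vector has cosine 0 by convention; the caller must skip
    restraints with |q12| = 0.
    """
    q12 = np.ravel(q12)
    b = np.ravel(bias_vec)
    nq = math.sqrt(float(q12 @ q12))
    if nq == 0.0:
        raise ValueError("coincident restrained atoms (|q12| = 0)")
    nb = math.sqrt(float(b @ b))
    if nb == 0.0:
        return 0.0
    return min(1.0, max(-1.0, float(b @ q12) / (nb * nq)))


def reweight_restrained_bias(bias_vec: np.ndarray, cos_val: float,
                             d12: float, d0: float) -> np.ndarray:
    """out = bias * cos(Xi) * sign(d12 - d0), with sign(0) = 0.

    |out| = |cos||bias| <= |bias| always; at exact fulfilment the
    reweighted bias vanishes.
    """
    diff = d12 - d0
    s = 0.0 if diff == 0.0 else float(np.sign(diff))
    return np.asarray(bias_vec, dtype=float) * (cos_val * s)


@dataclass
class RestraintGeometry:
    """Instantaneous geometry of one restraint: realizing pair and q12."""

    restraint_id: int
    atom1: int  # realizing group-1 atom
    atom2: int  # the single group-2 atom
    q12: np.ndarray  # q_atom1 - q_atom2, nm
    d12: float
    d0: float
    skip: bool = False

    @property
    def sign(self) -> float:
        diff = self.d12 - self.d0
        return 0.0 if diff == 0.0 else float(np.sign(diff))


def _reweight_terms(terms: dict, geometries) -> dict:
    """Apply the cosine reweighting to each bias term at restrained atoms.

    Multiple restraints touching one atom compose in record order (each
    further reduces the magnitude).
    """
    out = {name: t.copy() for name, t in terms.items()}
    for geom in geometries:
        if geom.skip:
            continue
        for t in out.values():
            for atom, sgn in ((geom.atom1, 1.0), (geom.atom2, -1.0)):
                c = cos_xi(t[atom], sgn * geom.q12)
                t[atom] = reweight_restrained_bias(t[atom], c, geom.d12, geom.d0)
    return out


def combine_restrained_gradients(bundle: GradientBundle, alpha_md: float,
                                 alpha_prime: float, geometries,
                                 per_atom: bool = False) -> np.ndarray:
    """Restrained total gradient: identical to :func:`combine_gradients`
    except that bias terms on restrained atoms are cosine-reweighted
    before summation."""
    terms = _scaled_terms(bundle, alpha_prime, per_atom)
    terms = _reweight_terms(terms, geometries)
    total = bundle.grad_A * (1.0 + alpha_md)
    for term in terms.values():
        total = total + term
    return total


def hybrid_energy(h_a: float, h_b: float, alpha_md: float, alpha_prime: float) -> float:
    """Scalar hybrid-energy diagnostic H(A)(1+a_md) + a' |H(A)|/|H(B)| H(B).

    Reported for bookkeeping only; propagation always uses the gradient
    combination, and the recorded potential energy of a run is V(A) alone.
    """
    if h_b == 0.0:
        return h_a * (1.0 + alpha_md)
    return h_a * (1.0 + alpha_md) + alpha_prime * abs(h_a) / abs(h_b) * h_b


def principal_component_bias(history: np.ndarray) -> np.ndarray | None:
    """Unit direction of the slowest mode of a window of bias vectors.

    Diagonalizes the covariance of the windowed samples and returns the
    eigenvector of the smallest eigenvalue (slowest mode), sign-fixed so
    its first nonzero component is positive.  Exact eigenvalue ties are
    broken toward the lowest coordinate axis inside the tied subspace.
    Returns None (with a warning) for rank-deficient windows, signalling
    the caller to fall back to the raw bias.
    """
    X = np.atleast_2d(np.asarray(history, dtype=float))
    n, d = X.shape
    if n < d:
        warnings.warn("PCA window smaller than dimension; using raw bias")
        return None
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / max(n - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    if vals[-1] <= 0 or vals[0] < 1e-12 * vals[-1]:
        warnings.warn("rank-deficient bias covariance; using raw bias")
        return None
    tie_tol = 1e-9 * vals[-1]
    tied = np.nonzero(vals <= vals[0] + tie_tol)[0]
    if len(tied) > 1:
        # project the lowest coordinate axis into the tied subspace
        vt = vecs[:, tied]
        for j in range(d):
            v = vt @ vt[j, :]
            nv = np.linalg.norm(v)
            if nv > 1e-12:
                direction = v / nv
                break
    else:
        direction = vecs[:, 0]
    for comp in direction:
        if abs(comp) > 1e-12:
            if comp < 0:
                direction = -direction
            break
    return direction


class BiasStack:
    """Per-step orchestration of the full biasing pipeline.

    Owns the path accumulator (adaptive-bias windows), the sigma state
    and hill history (path-sampling), the coupling draws, optional PCA
    filtering and the restraint reweighting.  ``step`` consumes the last
    integrator displacement and returns the extra gradient to apply on
    the next step together with per-step diagnostics.
    """

    def __init__(
        self,
        schedule,
        coupling: CouplingParams,
        n_atoms: int,
        dim: int,
        gamma_pp: float = 1e-4,
        hill_w: float = 0.1,
        hill_dsigma: float | None = None,
        dsigma_floor: float = 1e-4,
        delta_e: float = 1000.0,
        well_tempered: bool = False,
        use_pca: bool = False,
        pca_window_steps: int | None = None,
        per_atom_norm: bool = False,
        periodic: bool = False,
        period: float = 2.0 * np.pi,
    ):
        self.schedule = schedule
        self.coupling = coupling
        self.n_atoms = int(n_atoms)
        self.dim = int(dim)
        self.per_atom_norm = per_atom_norm
        self.periodic = periodic
        self.period = period
        self.acc = PathAccumulator(schedule, n_atoms, dim, gamma_pp=gamma_pp)
        self.sigma = SigmaState(schedule.n_r, n_atoms, dim)
        self.history = GaussianHistory(
            n_r=schedule.n_r,
            n_atoms=n_atoms,
            w=hill_w,
            delta_sigma=hill_dsigma,
            dsigma_floor=dsigma_floor,
            delta_e=delta_e,
            well_tempered=well_tempered,
        )
        self.use_pca = use_pca and dim > 1
        if pca_window_steps is None:
            pca_window_steps = int(schedule.n_r * schedule.steps1[0])
        self.pca_window = max(int(pca_window_steps), dim + 1)
        self._pca_buf = {
            "ab": np.zeros((self.pca_window, n_atoms, dim)),
            "sigma": np.zeros((self.pca_window, n_atoms, dim)),
        }
        self._pca_fill = 0
        self.step_count = 0
        self.max_restrained_excess = 0.0
        # one row per deposited hill: (t, rung, atom, sigma_center, W_eff);
        # together with delta_sigma this replays the bias potential exactly
        self.hill_log: list[tuple[float, int, int, float, float]] = []
        # countdown counters mirror step_count % steps{1,2} without array ops
        self._cnt1 = [int(s) for s in schedule.steps1]
        self._cnt2 = [int(s) for s in schedule.steps2]
        self._xi_block = np.empty(0)
        self._xi_pos = 0

    def _next_uniform_pair(self, rng):
        """Two uniforms from the coupling stream, drawn in blocks.

        Block drawing consumes the underlying bit stream in the same
        order as repeated scalar draws, so results are unchanged.
        """
        if self._xi_pos + 2 > len(self._xi_block):
            self._xi_block = rng.uniform(size=2048)
            self._xi_pos = 0
        xi = self._xi_block[self._xi_pos]
        xi_p = self._xi_block[self._xi_pos + 1]
        self._xi_pos += 2
        return xi, xi_p

    def validate(self, config) -> None:
        if abs(self.schedule.dt - config.dt) > 1e-12:
            raise ValueError(
                f"bias schedule built for dt={self.schedule.dt}, run uses {config.dt}"
            )

    def _apply_pca(self, name: str, raw: np.ndarray) -> np.ndarray:
        buf = self._pca_buf[name]
        buf[self.step_count % self.pca_window] = raw
        if self._pca_fill < self.pca_window:
            return raw
        out = raw.copy()
        for k in range(self.n_atoms):
            direction = principal_component_bias(buf[:, k, :])
            if direction is None:
                continue
            mag = np.linalg.norm(raw[k])
            out[k] = direction * mag
        return out

    def step(self, prev, curr, grad_A, system, restraints, rngs):
        """Advance the bias state by one integrator step.

        Returns ``(extra_gradient, diagnostics)``; the extra gradient is
        grad_A * alpha_md plus the renormalized (and, where restrained,
        reweighted) bias terms, so the engine's applied force is exactly
        the negative restrained hybrid gradient.
        """
        vec, scal = accumulate_dL(prev, curr, self.periodic, self.period)
        acc = self.acc
        acc.step_count += 1
        acc.window_vec += vec[None, :, :]
        acc.L += scal[None, :]
        chain = curr.p  # (p + dp) with p the pre-step momentum
        self.step_count += 1
        sg = self.sigma
        sg.sigma += scal[None, :]
        sg.chain = chain
        sg.step_stamp = self.step_count
        if self.history.delta_sigma is None:
            self.history.observe_sigma(sg.sigma[0])

        for i in range(self.schedule.n_r):
            self._cnt1[i] -= 1
            if self._cnt1[i] == 0:
                self._cnt1[i] = int(self.schedule.steps1[i])
                zeta = rngs["adaptive"].standard_normal(self.n_atoms)
                acc.close_window(i, zeta)

        t = self.step_count * self.schedule.dt
        for i in range(self.schedule.n_r):
            self._cnt2[i] -= 1
            if self._cnt2[i] == 0:
                self._cnt2[i] = int(self.schedule.steps2[i])
                self.history.deposit(i, sg.sigma[i], self.step_count)
                heights = self.history.heights[i][-1]
                for k in range(self.n_atoms):
                    self.hill_log.append(
                        (t, i, k, float(sg.sigma[i, k]), float(heights[k]))
                    )

        # all rungs share one sigma row, so the rung-summed hill force is
        # evaluated in a single pass; sigma_chain_rule gives the repulsive
        # force direction, and as a gradient entry it carries a minus sign
        # so that -grad pushes sigma away from the deposited hills
        phi_row = self.history.phi_sum(sg.sigma[0])
        b_ab = acc.total_gradient()
        b_sigma = -(phi_row[:, None] * chain)

        if self.use_pca:
            b_ab = self._apply_pca("ab", b_ab)
            b_sigma = self._apply_pca("sigma", b_sigma)
            self._pca_fill = min(self._pca_fill + 1, self.pca_window)

        xi, xi_p = self._next_uniform_pair(rngs["coupling"])
        alpha_md = self.coupling.eta_md * self.coupling.beta_md * (1.0 - xi)
        alpha_p = self.coupling.eta_prime * self.coupling.beta_prime * (1.0 - xi_p)
        bundle = GradientBundle(grad_A, b_ab, b_sigma)
        terms = _scaled_terms(bundle, alpha_p, self.per_atom_norm)

        geometries = []
        if restraints:
            from pathmd.restraints_io import effective_distance

            for rec in restraints:
                d12, q12, (a1, a2) = effective_distance(curr.q, rec)
                geometries.append(
                    RestraintGeometry(
                        restraint_id=rec.id, atom1=a1, atom2=a2,
                        q12=q12, d12=d12, d0=rec.d0, skip=(d12 == 0.0),
                    )
                )
            rterms = _reweight_terms(terms, geometries)
            # bookkeeping for the |restrained| <= |unrestrained| contract
            for name in terms:
                n_r = np.sqrt(np.sum(rterms[name] ** 2, axis=-1))
                n_u = np.sqrt(np.sum(terms[name] ** 2, axis=-1))
                excess = float(np.max(n_r - n_u, initial=0.0))
                self.max_restrained_excess = max(self.max_restrained_excess, excess)
        else:
            rterms = terms

        extra = grad_A * alpha_md
        for term in rterms.values():
            extra = extra + term

        diag = {
            "alpha_md": alpha_md,
            "alpha_prime": alpha_p,
            "bias_norm_ab": _norm(rterms["ab"]) if "ab" in rterms else 0.0,
            "bias_norm_sigma": _norm(rterms["sigma"]) if "sigma" in rterms else 0.0,
        }
        return extra, diag
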