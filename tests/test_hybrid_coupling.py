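import numpy as np
import pytest

from pathmd.action_bias import build_bias_schedule
from pathmd.engine import IntegratorConfig, run_trajectory
from pathmd.hybrid_coupling import (
    BiasStack,
    CouplingParams,
    GradientBundle,
    RestraintGeometry,
    combine_gradients,
    combine_restrained_gradients,
    cos_xi,
    draw_coupling,
    hybrid_energy,
    principal_component_bias,
    reweight_restrained_bias,
)
from pathmd.model_systems import make_bead_chain
from pathmd.restraints_io import RestraintRecord


class _FixedUniform:
    def __init__(self, values):
        self.values = list(values)

    def uniform(self, size=None):
        if size is None:
            return self.values.pop(0)
        out = np.array([self.values.pop(0) for _ in range(size)])
        return out


class TestDrawCoupling:
    def test_xi_one_gives_zero_coupling(self):
        params = CouplingParams(beta_md=1e-4, beta_prime=1e-4)
        a_md, a_p = draw_coupling(params, _FixedUniform([1.0, 1.0]))
        assert a_md == 0.0 and a_p == 0.0

    def test_xi_zero_gives_full_magnitude(self):
        params = CouplingParams(beta_md=1e-4, beta_prime=2e-4, eta_md=1.0, eta_prime=3.0)
        a_md, a_p = draw_coupling(params, _FixedUniform([0.0, 0.0]))
        assert a_md == pytest.approx(1e-4)
        assert a_p == pytest.approx(6e-4)

    def test_mean_is_half_eta_beta(self, rng):
        """<alpha> = eta*beta/2 within 3 sigma over 1e5 draws."""
        params = CouplingParams(beta_prime=1e-4, eta_prime=2.0)
        n = 100_000
        draws = np.array([draw_coupling(params, rng)[1] for _ in range(n)])
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - 1e-4) < 3 * se

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            CouplingParams(beta_md=-1.0)


class TestCombineGradients:
    def test_unbiased_limit_is_exact(self, rng):
        gA = rng.normal(size=(4, 3))
        bundle = GradientBundle(gA, rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        out = combine_gradients(bundle, 0.0, 0.0)
        assert np.array_equal(out, gA)

    def test_each_bias_term_is_rescaled_to_alpha_norm(self, rng):
        gA = rng.normal(size=(5, 3))
        b1 = rng.normal(size=(5, 3))
        bundle = GradientBundle(gA, b1, None)
        a_p = 0.01
        out = combine_gradients(bundle, 0.0, a_p)
        term = out - gA
        assert np.linalg.norm(term) == pytest.approx(
            a_p * np.linalg.norm(gA), rel=1e-12
        )

    def test_matches_independent_formula_recomputation(self, rng):
        """Term-by-term recomputation of the renormalized combination."""
        for _ in range(20):
            gA = rng.normal(size=(3, 2))
            b_ab = rng.normal(size=(3, 2))
            b_sg = rng.normal(size=(3, 2))
            a_md, a_p = 0.3 * rng.uniform(), 0.2 * rng.uniform()
            out = combine_gradients(GradientBundle(gA, b_ab, b_sg), a_md, a_p)
            nA = np.sqrt((gA**2).sum())
            expected = (
                gA * (1 + a_md)
                + b_ab * a_p * nA / np.sqrt((b_ab**2).sum())
                + b_sg * a_p * nA / np.sqrt((b_sg**2).sum())
            )
            assert np.allclose(out, expected, atol=1e-13)

    def test_zero_norm_terms_are_omitted(self, rng):
        gA = rng.normal(size=(2, 2))
        out = combine_gradients(GradientBundle(gA, np.zeros((2, 2)), None), 0.0, 0.1)
        assert np.array_equal(out, gA)

    def test_per_atom_variant_rescales_atomwise(self, rng):
        gA = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        out = combine_gradients(GradientBundle(gA, b, None), 0.0, 0.05, per_atom=True)
        term = out - gA
        for k in range(3):
            assert np.linalg.norm(term[k]) == pytest.approx(
                0.05 * np.linalg.norm(gA[k]), rel=1e-10
            )

    def test_nonfinite_norm_aborts(self):
        gA = np.array([[np.inf, 0.0]])
        with pytest.raises(FloatingPointError):
            combine_gradients(GradientBundle(gA, np.ones((1, 2)), None), 0.0, 0.1)


class TestCosXiAndReweighting:
    q12 = np.array([1.0, 0.0, 0.0])

    def test_parallel_perpendicular_antiparallel(self):
        assert cos_xi(np.array([2.0, 0, 0]), self.q12) == pytest.approx(1.0)
        assert cos_xi(np.array([0, 3.0, 0]), self.q12) == pytest.approx(0.0)
        assert cos_xi(np.array([-1.0, 0, 0]), self.q12) == pytest.approx(-1.0)

    def test_zero_bias_has_zero_cosine(self):
        assert cos_xi(np.zeros(3), self.q12) == 0.0

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError):
            cos_xi(np.ones(3), np.zeros(3))

    def test_exact_fulfilment_kills_the_bias(self):
        out = reweight_restrained_bias(np.array([1.0, 2.0, 3.0]), 0.8, 0.75, 0.75)
        assert np.all(out == 0.0)

    def test_aligned_bias_beyond_target_is_unchanged(self):
        b = np.array([0.0, 0.0, 2.0])
        out = reweight_restrained_bias(b, 1.0, 1.5, 0.75)
        assert np.array_equal(out, b)

    def test_half_overlap_below_target_flips_and_scales(self):
        b = np.array([2.0, 0.0, 0.0])
        out = reweight_restrained_bias(b, 0.5, 0.5, 0.75)
        assert np.allclose(out, -0.5 * b)

    def test_magnitude_never_grows(self, rng):
        for _ in range(200):
            b = rng.normal(size=3)
            c = rng.uniform(-1, 1)
            out = reweight_restrained_bias(b, c, rng.uniform(0.1, 2), 0.75)
            assert np.linalg.norm(out) <= np.linalg.norm(b) + 1e-12

    def test_reweighted_force_always_points_toward_fulfilment(self, rng):
        """For any bias direction, the force -reweighted_gradient moves
        the restrained atom toward d0: along -q12 when too far (atom 1),
        along +q12 when too close."""
        q12 = np.array([1.0, 0.0, 0.0])
        for _ in range(100):
            g = rng.normal(size=3)
            c = cos_xi(g, q12)
            # too far: d12 > d0
            force = -reweight_restrained_bias(g, c, 1.5, 0.75)
            assert force @ q12 <= 1e-12
            # too close: d12 < d0
            force = -reweight_restrained_bias(g, c, 0.3, 0.75)
            assert force @ q12 >= -1e-12


class TestCombineRestrained:
    def _geometry(self, q12, d12, d0=0.75, atoms=(0, 1)):
        return RestraintGeometry(0, atoms[0], atoms[1], np.asarray(q12, float),
                                 d12, d0)

    def test_without_restraints_equals_unrestrained(self, rng):
        gA = rng.normal(size=(3, 3))
        bundle = GradientBundle(gA, rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        a = combine_gradients(bundle, 0.1, 0.05)
        b = combine_restrained_gradients(bundle, 0.1, 0.05, [])
        assert np.array_equal(a, b)

    def test_orthogonal_overlap_strips_bias_from_restrained_atoms(self):
        gA = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        b_ab = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        bundle = GradientBundle(gA, b_ab, None)
        geom = self._geometry([1.0, 0.0, 0.0], d12=1.5, atoms=(0, 1))
        a_md = 0.2
        out = combine_restrained_gradients(bundle, a_md, 0.1, [geom])
        # restrained atoms keep only grad_A (1 + alpha_md)
        assert np.allclose(out[0], gA[0] * (1 + a_md))
        assert np.allclose(out[1], gA[1] * (1 + a_md))
        # the unrestrained atom keeps its bias term
        assert not np.allclose(out[2], gA[2] * (1 + a_md))

    def test_matches_term_by_term_oracle(self, rng):
        """Random configuration against an independent recomputation of
        the restrained combination."""
        for _ in range(20):
            gA = rng.normal(size=(4, 3))
            b_ab = rng.normal(size=(4, 3))
            b_sg = rng.normal(size=(4, 3))
            a_md, a_p = 0.1 * rng.uniform(), 0.05 * rng.uniform()
            q12 = rng.normal(size=3)
            d12, d0 = rng.uniform(0.2, 2.0), 0.75
            geom = self._geometry(q12, d12, d0, atoms=(1, 3))
            bundle = GradientBundle(gA, b_ab, b_sg)
            out = combine_restrained_gradients(bundle, a_md, a_p, [geom])

            nA = np.linalg.norm(gA)
            sgn = np.sign(d12 - d0)
            expected = gA * (1 + a_md)
            for B in (b_ab, b_sg):
                term = B * a_p * nA / np.linalg.norm(B)
                for atom, s in ((1, 1.0), (3, -1.0)):
                    v = term[atom]
                    c = float(v @ (s * q12) / (np.linalg.norm(v) * np.linalg.norm(q12)))
                    term = term.copy()
                    term[atom] = v * c * sgn
                expected = expected + term
            assert np.allclose(out, expected, atol=1e-12)

    def test_skipped_geometry_leaves_terms_alone(self, rng):
        gA = rng.normal(size=(2, 3))
        bundle = GradientBundle(gA, rng.normal(size=(2, 3)), None)
        geom = self._geometry([0.0, 0.0, 0.0], d12=0.0)
        geom.skip = True
        out = combine_restrained_gradients(bundle, 0.0, 0.1, [geom])
        assert np.array_equal(out, combine_gradients(bundle, 0.0, 0.1))


class TestHybridEnergyDiagnostic:
    def test_zero_bias_energy(self):
        assert hybrid_energy(-12.0, 0.0, 0.1, 0.5) == pytest.approx(-12.0 * 1.1)

    def test_scalar_combination(self):
        # H(A)(1+a_md) + a'|H(A)|/|H(B)| H(B)
        assert hybrid_energy(10.0, -2.0, 0.0, 0.1) == pytest.approx(
            10.0 + 0.1 * 10.0 / 2.0 * (-2.0)
        )


class TestPrincipalComponentBias:
    def test_diagonal_variances_select_smallest_axis(self, rng):
        n = 400
        X = rng.normal(size=(n, 3)) * np.sqrt([3.0, 1.0, 2.0])
        d = principal_component_bias(X)
        assert abs(d[1]) > 0.99
        first = np.nonzero(np.abs(d) > 1e-12)[0][0]
        assert d[first] > 0  # sign convention: first nonzero component positive

    def test_isotropic_tie_breaks_to_lowest_axis(self):
        # perfectly isotropic covariance via symmetric design
        X = np.array([
            [1.0, 0, 0], [-1.0, 0, 0],
            [0, 1.0, 0], [0, -1.0, 0],
            [0, 0, 1.0], [0, 0, -1.0],
        ])
        d = principal_component_bias(X)
        assert np.allclose(d, [1.0, 0.0, 0.0])

    def test_matches_bruteforce_eigendecomposition(self, rng):
        """5-D window against an independent np.linalg.eig of np.cov."""
        X = rng.normal(size=(60, 5)) * np.array([2.0, 0.5, 1.0, 3.0, 0.9])
        d = principal_component_bias(X)
        vals, vecs = np.linalg.eig(np.cov(X, rowvar=False))
        v = np.real(vecs[:, np.argmin(np.real(vals))])
        if v[np.nonzero(np.abs(v) > 1e-12)[0][0]] < 0:
            v = -v
        assert np.allclose(np.abs(d @ v), 1.0, atol=1e-10)
        assert np.allclose(d, v, atol=1e-10)

    def test_rank_deficient_window_falls_back(self):
        with pytest.warns(UserWarning):
            assert principal_component_bias(np.zeros((10, 3))) is None
        with pytest.warns(UserWarning):
            assert principal_component_bias(np.ones((2, 3))) is None


class TestBiasStackContracts:
    def test_restrained_bias_never_exceeds_unrestrained(self):
        """Per-atom |restrained bias| <= |bias| along a whole run."""
        chain = make_bead_chain(8)
        sched = build_bias_schedule(3, 0.05, 0.1, dt=0.005)
        stack = BiasStack(sched, CouplingParams(eta_prime=2000.0),
                          n_atoms=8, dim=3)
        rec = RestraintRecord(0, [0], [6], 0.75)
        cfg = IntegratorConfig(dt=0.005, seed=21)
        run_trajectory(chain, cfg, bias_stack=stack, restraints=[rec],
                       n_steps=2000, stride=100)
        assert stack.max_restrained_excess <= 1e-12

    def test_validate_rejects_mismatched_timestep(self):
        sched = build_bias_schedule(2, 1.0, 2.5, dt=0.001)
        stack = BiasStack(sched, CouplingParams(), n_atoms=1, dim=1)
        with pytest.raises(ValueError):
            stack.validate(IntegratorConfig(dt=0.005))


class TestHillLogReplay:
    def test_hill_log_replays_the_bias_potential_exactly(self):
        """Rebuilding the Gaussian history from the hill log (plus the
        calibrated width) reproduces the live hill forces."""
        from pathmd.config import build_run, resolve_config
        from pathmd.engine import run_trajectory
        from pathmd.path_metadynamics import GaussianHistory

        cfg = resolve_config({"seed": 13, "system": {"name": "bead_chain", "n": 4}})
        system, integ, bias, _ = build_run(cfg)
        run_trajectory(system, integ, bias_stack=bias, n_steps=4000, stride=200)
        live = bias.history
        assert live.n_hills(0) > 0
        replay = GaussianHistory(n_r=bias.schedule.n_r, n_atoms=4,
                                 delta_sigma=live.delta_sigma)
        per_event = {}
        for t, i, k, center, w in bias.hill_log:
            per_event.setdefault((t, i), [0.0] * 4)[k] = center
            assert w == live.w  # no well-tempering by default
        for step, ((t, i), centers) in enumerate(sorted(per_event.items()), 1):
            replay.deposit(i, np.array(centers), step)
        sig = bias.sigma.sigma
        assert np.allclose(replay.phi(sig), live.phi(sig), atol=1e-12)
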