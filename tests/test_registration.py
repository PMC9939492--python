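"""Objective assembly, optimizer behavior, and pair registration."""

import warnings

import numpy as np
import pytest

from atlasguide import (
    DisplacementField,
    ImageGrid,
    PhantomSpec,
    ScalarVolume,
    jacobian_determinant,
    make_phantom,
)
from atlasguide.guidance import landmark_penalty, mask_penalty, matched_landmarks, warped_mask_values
from atlasguide.registration import (
    PairRegistration,
    RegistrationConfig,
    downsample_mask,
    downsample_scalar,
    lbfgs,
    objective,
    pre_align,
    prolong_displacement,
    resolve_edge_parameters,
)
from atlasguide.regularizers import curvature_energy, volume_penalty
from atlasguide.similarity import EdgeParameters, ngf_distance
from atlasguide.image_model import warp

from conftest import smooth_random_field, smooth_random_volume, toy_guidance


def small_phantom(seed=0, noise_sd=0.02):
    """Full anatomy on a coarse 24-cube (2 mm voxels) for fast registrations."""
    return make_phantom(PhantomSpec(shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0),
                                    noise_sd=noise_sd, seed=seed))


@pytest.fixture
def instance(grid8):
    R = smooth_random_volume(grid8, seed=40)
    T = smooth_random_volume(grid8, seed=41)
    field = smooth_random_field(grid8, seed=42, amplitude=0.4)
    gR = toy_guidance(grid8)
    gT = toy_guidance(grid8, jitter=0.4)
    cfg = RegistrationConfig(eps=(0.4, 0.35))
    return R, T, field, gR, gT, cfg


class TestObjective:
    def test_zero_at_identity_with_identical_inputs(self, grid8):
        R = smooth_random_volume(grid8, seed=50)
        g = toy_guidance(grid8)
        cfg = RegistrationConfig(eps=(0.3, 0.3))
        value, grad = objective(R, R, DisplacementField.zeros(grid8), g, g, cfg)
        assert value == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(grad, 0.0, atol=1e-10)

    def test_fold_returns_infinity(self, instance):
        R, T, _, gR, gT, cfg = instance
        x = R.grid.world_coordinates()
        folded = DisplacementField(R.grid, -2.0 * (x - x.mean(axis=(0, 1, 2))))
        value, grad = objective(R, T, folded, gR, gT, cfg)
        assert np.isinf(value)
        assert grad is None

    def test_equals_sum_of_independent_terms(self, instance):
        R, T, field, gR, gT, cfg = instance
        terms = {}
        value, _ = objective(R, T, field, gR, gT, cfg, terms_out=terms)
        eps = EdgeParameters(*cfg.eps)

        Tw = warp(T, field, mode="linear")
        ngf_val, _ = ngf_distance(R, Tw, eps)
        cv_val, _ = curvature_energy(field)
        vp_val, _ = volume_penalty(field)
        mk = 0.0
        for name in ("BP",):
            mw, _ = warped_mask_values(gT.masks[name], field)
            mk += mask_penalty(mw, gR.masks[name])[0]
        mw, _ = warped_mask_values(gT.ventricle_union, field)
        mk += mask_penalty(mw, gR.ventricle_union)[0]
        r, t = matched_landmarks(gR, gT)
        lm_val, _ = landmark_penalty(field, r, t)

        oracle = (ngf_val + cfg.alpha * cv_val + cfg.beta * vp_val
                  + cfg.gamma * mk + cfg.delta * lm_val)
        assert value == pytest.approx(oracle, rel=1e-12)
        assert terms["ngf"] == pytest.approx(ngf_val, rel=1e-12)
        assert terms["landmark"] == pytest.approx(cfg.delta * lm_val, rel=1e-12)

    def test_gradient_matches_central_differences(self, instance):
        R, T, field, gR, gT, cfg = instance
        value, grad = objective(R, T, field, gR, gT, cfg)
        assert np.isfinite(value)
        rng = np.random.default_rng(43)
        d = rng.standard_normal(grad.shape)
        d /= np.abs(d).max()
        # step small enough that the difference quotient does not straddle a
        # trilinear cell face (the interpolant is only piecewise smooth)
        h = 1e-6
        fp, _ = objective(R, T, DisplacementField(R.grid, field.u + h * d), gR, gT, cfg)
        fm, _ = objective(R, T, DisplacementField(R.grid, field.u - h * d), gR, gT, cfg)
        assert np.sum(grad * d) == pytest.approx((fp - fm) / (2 * h), rel=1e-4)

    def test_grid_mismatch_rejected(self, instance):
        R, T, field, gR, gT, cfg = instance
        bad = DisplacementField.zeros(ImageGrid((8, 8, 8), (2.0, 1.2, 0.9)))
        with pytest.raises(ValueError):
            objective(R, T, bad, gR, gT, cfg)


class TestPreAlign:
    def test_identical_inputs_zero_field(self, grid8):
        R = smooth_random_volume(grid8, seed=60)
        g = toy_guidance(grid8)
        field = pre_align(R, R, g, g)
        np.testing.assert_allclose(field.u, 0.0, atol=1e-9)

    def test_translation_recovers_centroid_shift(self):
        ph = small_phantom()
        shift = np.array([6.0, 0.0, 0.0])
        shifted_grid = ImageGrid(ph.grid.shape, ph.grid.spacing,
                                 tuple(np.asarray(ph.grid.origin) + shift))
        from atlasguide import MaskVolume
        from atlasguide.guidance import build_guidance_set

        g_shift = build_guidance_set(
            {k: MaskVolume(shifted_grid, m.values) for k, m in ph.guidance.masks.items()})
        T_shift = ScalarVolume(shifted_grid, ph.mr.values)
        field = pre_align(ph.ct, T_shift, ph.guidance, g_shift)
        np.testing.assert_allclose(field.u[0, 0, 0], shift, atol=1e-9)
        np.testing.assert_allclose(jacobian_determinant(field).values, 1.0, atol=1e-12)

    def test_empty_bp_mask_warns_zero_field(self, grid8):
        from atlasguide import MaskVolume
        from atlasguide.guidance import build_guidance_set

        R = smooth_random_volume(grid8, seed=61)
        g_ok = toy_guidance(grid8)
        g_empty = build_guidance_set({
            "BP": MaskVolume(grid8, np.zeros(grid8.shape, dtype=np.uint8)),
            "LLV": g_ok.masks["LLV"],
        })
        with pytest.warns(UserWarning, match="parenchyma"):
            field = pre_align(R, R, g_ok, g_empty)
        np.testing.assert_array_equal(field.u, 0.0)


class TestPyramid:
    def test_downsample_halves_shape_and_doubles_spacing(self, grid8):
        v = smooth_random_volume(grid8, seed=70)
        d = downsample_scalar(v)
        assert d.grid.shape == (4, 4, 4)
        assert d.grid.spacing == tuple(2 * s for s in grid8.spacing)
        # block means preserved
        assert d.values[0, 0, 0] == pytest.approx(v.values[:2, :2, :2].mean())

    def test_downsample_mask_majority(self, grid8):
        from conftest import ball_mask

        m = ball_mask(grid8, radius=3.0)
        d = downsample_mask(m)
        assert set(np.unique(d.values)) <= {0, 1}
        assert d.n_foreground > 0

    def test_prolongation_preserves_constant_field(self, grid8):
        coarse = ImageGrid((4, 4, 4), tuple(2 * s for s in grid8.spacing),
                           tuple(o + 0.5 * s for o, s in zip(grid8.origin, grid8.spacing)))
        u = np.zeros((4, 4, 4, 3))
        u[:] = (1.5, -0.5, 2.0)
        fine = prolong_displacement(DisplacementField(coarse, u), grid8)
        np.testing.assert_allclose(fine.u[..., 0], 1.5, atol=1e-12)
        np.testing.assert_allclose(fine.u[..., 2], 2.0, atol=1e-12)


class TestLbfgs:
    def test_quadratic_bowl_converges(self):
        A = np.diag([1.0, 10.0, 100.0])
        b = np.array([1.0, -2.0, 3.0])

        def fun(x):
            return 0.5 * x @ A @ x - b @ x, A @ x - b

        x, trace, msgs = lbfgs(fun, np.zeros(3), max_iters=200, grad_tol_rel=1e-10)
        np.testing.assert_allclose(x, np.linalg.solve(A, b), atol=1e-6)
        assert not msgs
        assert all(t2 <= t1 + 1e-12 for t1, t2 in zip(trace, trace[1:]))

    def test_rejects_infinite_steps(self):
        # objective is +inf beyond |x| > 1: line search must backtrack into the ball
        def fun(x):
            if np.abs(x).max() > 1.0:
                return np.inf, None
            return float((x[0] - 5.0) ** 2), np.array([2 * (x[0] - 5.0)])

        x, trace, _ = lbfgs(fun, np.zeros(1), max_iters=50, step_cap=10.0)
        assert np.abs(x).max() <= 1.0
        assert all(np.isfinite(trace))


class TestRegister:
    def test_identity_recovery(self):
        ph = small_phantom()
        cfg = RegistrationConfig(levels=2, max_iters_per_level=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = PairRegistration(ph.ct, ph.ct, ph.guidance, ph.guidance, cfg).fit()
        mean_u = np.sqrt(np.sum(res.field.u**2, -1)).mean()
        assert mean_u < 0.1 * max(ph.grid.spacing)
        assert res.min_jacobian > 0

    def test_trace_monotone_and_foldfree_on_hard_pair(self):
        ph = small_phantom(seed=1)
        from atlasguide import deform_phantom, random_smooth_field

        gt = random_smooth_field(ph.grid, 3.0, 10.0, seed=11)
        target = deform_phantom(ph, gt)
        cfg = RegistrationConfig(levels=2, max_iters_per_level=(25, 12))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = PairRegistration(target.ct, ph.mr, target.guidance, ph.guidance, cfg).fit()
        for trace in res.objective_trace:
            assert all(t2 <= t1 + 1e-9 for t1, t2 in zip(trace, trace[1:]))
        assert res.min_jacobian > 0
        assert set(res.term_values) == {"ngf", "curvature", "volume", "mask",
                                        "landmark", "total"}

    def test_summary_mentions_key_quantities(self):
        ph = small_phantom()
        cfg = RegistrationConfig(levels=1, max_iters_per_level=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = PairRegistration(ph.ct, ph.mr, ph.guidance, ph.guidance, cfg).fit()
        text = res.summary()
        assert "min det" in text and "level 0" in text


class TestConfig:
    def test_rejects_unknown_and_invalid_fields(self):
        with pytest.raises(TypeError):
            RegistrationConfig(nonsense=1)
        with pytest.raises(ValueError):
            RegistrationConfig(alpha=-1)
        with pytest.raises(ValueError):
            RegistrationConfig(levels=0)

    def test_per_level_iteration_schedule(self):
        cfg = RegistrationConfig(max_iters_per_level=(80, 40, 20))
        assert cfg.iters_for_level(0, 3) == 80
        assert cfg.iters_for_level(2, 3) == 20
        assert RegistrationConfig(max_iters_per_level=50).iters_for_level(1, 3) == 50

    def test_auto_eps_positive(self, grid8):
        R = smooth_random_volume(grid8, seed=80)
        eps = resolve_edge_parameters(R, R, RegistrationConfig())
        assert eps.eps_R > 0 and eps.eps_T > 0

    def test_roundtrips_to_dict(self):
        cfg = RegistrationConfig(alpha=2.5, max_iters_per_level=(10, 5))
        d = cfg.to_dict()
        cfg2 = RegistrationConfig(**d)
        assert cfg2.alpha == 2.5
        assert tuple(cfg2.max_iters_per_level) == (10, 5)
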