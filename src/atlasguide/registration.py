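"""Guided variational registration: objective assembly and multi-level L-BFGS.

The registration estimates a displacement field ``u`` (deformation
``y(x) = x + u(x)``) minimizing

    J(R, T(y)) = NGF(R, T(y))
               + alpha/2 * sum_k ||Laplacian(y_k)||^2
               + beta    * integral psi(det grad y)
               + gamma/2 * ( ||M_BP^T(y) - M_BP^R||^2 + ||M_V^T(y) - M_V^R||^2 )
               + delta/2 * sum_l ||y(r_l) - t_l||^2

where R is the fixed (CT-like) image, T the moving (MR-like) template,
M the brain-parenchyma / ventricle-union guidance masks, and (r_l, t_l)
corresponding ventricle centers of gravity.  The psi barrier makes the
objective +inf at any fold (det <= 0), and the monotone Armijo line search
rejects such steps outright, so every accepted iterate is fold-free.

Optimization runs coarse to fine over a factor-2 image pyramid with a
limited-memory BFGS quasi-Newton method; the displacement (in mm, hence
resolution independent) is prolonged between levels by trilinear
interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as _dfield

import numpy as np

from .image_model import (
    DisplacementField,
    ImageGrid,
    MaskVolume,
    ScalarVolume,
    jacobian_determinant,
    trilinear_sample,
)
from .guidance import (
    GuidanceSet,
    build_guidance_set,
    center_of_gravity,
    landmark_penalty,
    mask_penalty,
    matched_landmarks,
    warped_mask_values,
)
from .regularizers import curvature_energy, volume_penalty
from .similarity import EdgeParameters, estimate_edge_parameter, ngf_distance

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "PairRegistration",
    "objective",
    "register",
    "pre_align",
]

log = logging.getLogger(__name__)


class RegistrationConfig:
    """Tunable parameters of the guided registration.

    The energy weights (``alpha`` curvature, ``beta`` volume penalty,
    ``gamma`` mask guidance, ``delta`` landmark guidance) are repository
    defaults tuned on the synthetic phantom suite.  ``eps`` is either a
    ``(eps_R, eps_T)`` pair or ``"auto"``, in which case each image's edge
    parameter is estimated per pyramid level as ``eps_fraction`` times its
    mean gradient magnitude.  ``max_iters_per_level`` may be a single int or
    a sequence ordered coarse to fine.
    """

    alpha = 40.0
    beta = 0.1
    gamma = 10.0
    delta = 5.0
    eps = "auto"
    eps_fraction = 0.1
    levels = 3
    lbfgs_memory = 10
    max_iters_per_level = 100
    grad_tol = 1e-3
    armijo_c = 1e-4
    max_backtracks = 25
    prealign_scale = False
    seed = 0

    def __init__(self, **kwargs):
        for k, v in kwargs.items():
            if not hasattr(type(self), k):
                raise TypeError(f"unknown config field {k!r}")
            setattr(self, k, v)
        for k in ("alpha", "beta", "gamma", "delta"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be non-negative")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.grad_tol <= 0 or self.eps_fraction <= 0:
            raise ValueError("tolerances must be positive")
        if self.lbfgs_memory < 1:
            raise ValueError("lbfgs_memory must be >= 1")

    def iters_for_level(self, level: int, n_levels: int) -> int:
        """Iteration cap for ``level`` (0 = coarsest)."""
        m = self.max_iters_per_level
        if np.isscalar(m):
            return int(m)
        m = list(m)
        return int(m[min(level, len(m) - 1)])

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "alpha", "beta", "gamma", "delta", "eps", "eps_fraction",
                "levels", "lbfgs_memory", "max_iters_per_level", "grad_tol",
                "armijo_c", "max_backtracks", "prealign_scale", "seed",
            )
        }
        if not np.isscalar(d["max_iters_per_level"]):
            d["max_iters_per_level"] = list(d["max_iters_per_level"])
        if d["eps"] != "auto":
            d["eps"] = list(d["eps"])
        return d


@dataclass
class RegistrationResult:
    """Outcome of a pair registration.

    ``objective_trace`` holds one monotonically non-increasing list of
    objective values per pyramid level (coarse first); ``term_values`` the
    weighted final value of each energy term on the full-resolution grid;
    ``min_jacobian`` the smallest Jacobian determinant of the returned
    deformation (> 0 by construction).
    """

    field: DisplacementField
    objective_trace: list
    term_values: dict
    min_jacobian: float
    converged: bool = True
    messages: list = _dfield(default_factory=list)

    def summary(self) -> str:
        lines = ["Guided registration result", "=" * 40]
        lines.append(f"grid:          {self.field.grid.shape}, spacing {self.field.grid.spacing} mm")
        umag = np.sqrt(np.einsum("...k,...k->...", self.field.u, self.field.u))
        lines.append(f"|u| mean/max:  {umag.mean():.3f} / {umag.max():.3f} mm")
        lines.append(f"min det(grad y): {self.min_jacobian:.4f}")
        lines.append("energy terms (weighted):")
        for name, val in self.term_values.items():
            lines.append(f"  {name:<12} {val: .6g}")
        for lvl, trace in enumerate(self.objective_trace):
            lines.append(
                f"level {lvl}: {len(trace) - 1} iterations, "
                f"J {trace[0]:.6g} -> {trace[-1]:.6g}"
            )
        lines.append(f"converged:     {self.converged}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Objective


def _grids_equal(a: ImageGrid, b: ImageGrid) -> bool:
    return a.shape == b.shape and a.spacing == b.spacing and a.origin == b.origin


def _warped_intensity(T: ScalarVolume, field: DisplacementField):
    points = field.deformed_points()
    idx = T.grid.world_to_index(points)
    vals, didx = trilinear_sample(T.values, idx, with_gradient=True)
    return vals, didx / np.asarray(T.grid.spacing)


def objective(
    R: ScalarVolume,
    T: ScalarVolume,
    field: DisplacementField,
    guidance_R: GuidanceSet,
    guidance_T: GuidanceSet,
    config: RegistrationConfig,
    *,
    eps: EdgeParameters | None = None,
    terms_out: dict | None = None,
):
    """Full objective value and gradient with respect to ``u``.

    Returns ``(value, grad)`` with ``grad`` of shape ``(*R.grid.shape, 3)``;
    when any voxel folds (det <= 0) the value is ``+inf`` and the gradient is
    ``None``.  ``terms_out``, when given, receives the weighted value of each
    term.
    """
    if not _grids_equal(R.grid, field.grid) or not _grids_equal(R.grid, guidance_R.grid):
        raise ValueError("fixed image, guidance and displacement field must share one grid")
    if not _grids_equal(T.grid, guidance_T.grid):
        raise ValueError("moving image and its guidance must share one grid")

    # barrier first: a folded field short-circuits everything else
    vp_val, vp_grad = volume_penalty(field)
    if not np.isfinite(vp_val):
        if terms_out is not None:
            terms_out.update({"ngf": np.nan, "curvature": np.nan,
                              "volume": np.inf, "mask": np.nan, "landmark": np.nan})
        return np.inf, None

    if eps is None:
        eps = resolve_edge_parameters(R, T, config)

    grad = np.zeros_like(field.u)

    Tw_vals, dTdy = _warped_intensity(T, field)
    ngf_val, ngf_gradTw = ngf_distance(R, ScalarVolume(R.grid, Tw_vals), eps)
    grad += ngf_gradTw[..., None] * dTdy

    cv_val, cv_grad = curvature_energy(field)
    grad += config.alpha * cv_grad
    grad += config.beta * vp_grad

    mk_val = 0.0
    pairs = []
    if "BP" in guidance_R.masks and "BP" in guidance_T.masks:
        pairs.append((guidance_T.masks["BP"], guidance_R.masks["BP"]))
    vr, vt = guidance_R.ventricle_union, guidance_T.ventricle_union
    pairs.append((vt, vr))
    any_guidance = any(m.n_foreground > 0 for m, _ in pairs)
    if config.gamma > 0 and not any_guidance:
        warnings.warn("all guidance masks empty; mask term contributes 0", stacklevel=2)
    for moving_mask, fixed_mask in pairs:
        if moving_mask.n_foreground == 0 and fixed_mask.n_foreground == 0:
            continue
        mw, dmdy = warped_mask_values(moving_mask, field)
        v, g_mw = mask_penalty(mw, fixed_mask)
        mk_val += v
        grad += config.gamma * g_mw[..., None] * dmdy

    r_pts, t_pts = matched_landmarks(guidance_R, guidance_T)
    if config.delta > 0 and len(r_pts) == 0 and not guidance_R.cogs and not guidance_T.cogs:
        warnings.warn("no ventricle landmarks available; landmark term contributes 0",
                      stacklevel=2)
    lm_val, lm_grad = landmark_penalty(field, r_pts, t_pts)
    grad += config.delta * lm_grad

    value = (
        ngf_val
        + config.alpha * cv_val
        + config.beta * vp_val
        + config.gamma * mk_val
        + config.delta * lm_val
    )
    if terms_out is not None:
        terms_out.update(
            {
                "ngf": ngf_val,
                "curvature": config.alpha * cv_val,
                "volume": config.beta * vp_val,
                "mask": config.gamma * mk_val,
                "landmark": config.delta * lm_val,
            }
        )
    return value, grad


def resolve_edge_parameters(R: ScalarVolume, T: ScalarVolume,
                            config: RegistrationConfig) -> EdgeParameters:
    if config.eps == "auto":
        return EdgeParameters(
            estimate_edge_parameter(R, config.eps_fraction),
            estimate_edge_parameter(T, config.eps_fraction),
        )
    eR, eT = config.eps
    return EdgeParameters(float(eR), float(eT))


# ---------------------------------------------------------------------------
# Pre-alignment


def pre_align(R: ScalarVolume, T: ScalarVolume, guidance_R: GuidanceSet,
              guidance_T: GuidanceSet, *, scale: bool = False) -> DisplacementField:
    """Initial field: constant translation of the moving BP centroid onto the fixed one.

    With ``scale`` the map becomes ``y(x) = c_T + s * (x - c_R)`` with the
    isotropic factor ``s = (V_T / V_R)^(1/3)`` from the BP mask volumes
    (det = s^3 > 0).  Empty BP masks fall back to the zero field with a
    warning.
    """
    bp_R = guidance_R.masks.get("BP")
    bp_T = guidance_T.masks.get("BP")
    if bp_R is None or bp_T is None or bp_R.n_foreground == 0 or bp_T.n_foreground == 0:
        warnings.warn("empty brain-parenchyma mask; zero initialization", stacklevel=2)
        return DisplacementField.zeros(R.grid)
    c_R = center_of_gravity(bp_R)
    c_T = center_of_gravity(bp_T)
    x = R.grid.world_coordinates()
    if scale:
        s = (bp_T.n_foreground * bp_T.grid.voxel_volume
             / (bp_R.n_foreground * bp_R.grid.voxel_volume)) ** (1.0 / 3.0)
        u = c_T + s * (x - c_R) - x
    else:
        u = np.broadcast_to(c_T - c_R, x.shape).copy()
    return DisplacementField(R.grid, u)


# ---------------------------------------------------------------------------
# Pyramid


def _pad_to_even(vals: np.ndarray) -> np.ndarray:
    pads = [(0, n % 2) for n in vals.shape]
    if any(p[1] for p in pads):
        vals = np.pad(vals, pads, mode="edge")
    return vals


def downsample_grid(grid: ImageGrid) -> ImageGrid:
    return ImageGrid(
        tuple(-(-n // 2) for n in grid.shape),
        tuple(2 * s for s in grid.spacing),
        tuple(o + 0.5 * s for o, s in zip(grid.origin, grid.spacing)),
    )


def downsample_scalar(volume: ScalarVolume) -> ScalarVolume:
    v = _pad_to_even(volume.values)
    v = v.reshape(v.shape[0] // 2, 2, v.shape[1] // 2, 2, v.shape[2] // 2, 2)
    return ScalarVolume(downsample_grid(volume.grid), v.mean(axis=(1, 3, 5)))


def downsample_mask(mask: MaskVolume) -> MaskVolume:
    v = _pad_to_even(mask.values.astype(float))
    v = v.reshape(v.shape[0] // 2, 2, v.shape[1] // 2, 2, v.shape[2] // 2, 2)
    return MaskVolume(downsample_grid(mask.grid), (v.mean(axis=(1, 3, 5)) >= 0.5).astype(np.uint8))


def _downsample_side(image: ScalarVolume, guidance: GuidanceSet, n_levels: int):
    """Fine-to-coarse pyramids of one image and its guidance masks.

    COGs are recomputed from the pooled masks at every level; a small
    structure (typically the fourth ventricle) whose pooled mask becomes
    empty keeps the next-finer level's COG instead — the landmark is a
    world-space point and stays meaningful exactly where the mask term has
    lost the structure.
    """
    images, guides = [image], [guidance]
    for _ in range(n_levels - 1):
        image = downsample_scalar(image)
        masks = {k: downsample_mask(m) for k, m in guides[-1].masks.items()}
        images.append(image)
        coarse = build_guidance_set(masks)
        for name, cog in guides[-1].cogs.items():
            coarse.cogs.setdefault(name, cog)
        guides.append(coarse)
    return images, guides


def prolong_displacement(field: DisplacementField, fine_grid: ImageGrid) -> DisplacementField:
    """Trilinear prolongation of ``u`` (mm) onto a finer grid, edge-clamped."""
    idx = field.grid.world_to_index(fine_grid.world_coordinates())
    idx = np.clip(idx, 0.0, np.asarray(field.grid.shape, dtype=float) - 1.0)
    u = np.empty((*fine_grid.shape, 3))
    for k in range(3):
        u[..., k] = trilinear_sample(field.u[..., k], idx)
    return DisplacementField(fine_grid, u)


# ---------------------------------------------------------------------------
# L-BFGS with Armijo backtracking


def _two_loop(g, s_list, y_list):
    q = g.copy()
    alphas = []
    for s, y in zip(reversed(s_list), reversed(y_list)):
        rho = 1.0 / np.dot(y, s)
        a = rho * np.dot(s, q)
        alphas.append(a)
        q -= a * y
    if s_list:
        s, y = s_list[-1], y_list[-1]
        q *= np.dot(s, y) / np.dot(y, y)
    for (s, y), a in zip(zip(s_list, y_list), reversed(alphas)):
        rho = 1.0 / np.dot(y, s)
        b = rho * np.dot(y, q)
        q += (a - b) * s
    return -q


def lbfgs(fun, x0, *, memory=10, max_iters=100, grad_tol_rel=1e-3,
          armijo_c=1e-4, max_backtracks=25, step_cap=1.0):
    """Monotone limited-memory BFGS.

    ``fun`` returns ``(value, gradient)``; infinite values signal the fold
    barrier and are rejected by the backtracking line search, so the trace of
    accepted objective values is non-increasing and every accepted iterate is
    feasible.  Convergence when the gradient max-norm drops below
    ``grad_tol_rel`` times its initial value.
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g = fun(x)
    if not np.isfinite(f):
        raise ValueError("initial iterate has infinite objective (folded field)")
    trace = [f]
    g0_norm = np.max(np.abs(g))
    tol = grad_tol_rel * g0_norm
    s_list, y_list = [], []
    messages = []
    for _ in range(max_iters):
        gnorm = np.max(np.abs(g))
        if gnorm <= tol or gnorm == 0.0:
            break
        d = _two_loop(g, s_list, y_list)
        gd = np.dot(g, d)
        if gd >= 0:  # safeguard: fall back to steepest descent
            d = -g
            gd = -np.dot(g, g)
        if not s_list:
            # first step: cap the largest displacement change
            t = min(1.0, step_cap / max(np.max(np.abs(d)), 1e-30))
        else:
            t = 1.0
        accepted = False
        for _bt in range(max_backtracks + 1):
            xn = x + t * d
            fn, gn = fun(xn)
            if np.isfinite(fn) and fn <= f + armijo_c * t * gd:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            messages.append("line search failed; terminating level early")
            break
        s = xn - x
        yv = gn - g
        if np.dot(s, yv) > 1e-10 * np.linalg.norm(s) * np.linalg.norm(yv):
            s_list.append(s)
            y_list.append(yv)
            if len(s_list) > memory:
                s_list.pop(0)
                y_list.pop(0)
        x, f, g = xn, fn, gn
        trace.append(f)
    return x, trace, messages


# ---------------------------------------------------------------------------
# Multi-level driver


class PairRegistration:
    """Registration model for one fixed/moving image pair.

    Parameters mirror :func:`objective`; :meth:`fit` runs the multi-level
    optimization and returns a :class:`RegistrationResult`.
    """

    def __init__(self, fixed: ScalarVolume, moving: ScalarVolume,
                 fixed_guidance: GuidanceSet, moving_guidance: GuidanceSet,
                 config: RegistrationConfig | None = None):
        self.fixed = fixed
        self.moving = moving
        self.fixed_guidance = fixed_guidance
        self.moving_guidance = moving_guidance
        self.config = config or RegistrationConfig()

    def fit(self) -> RegistrationResult:
        cfg = self.config
        n_levels = cfg.levels
        fixed_imgs, fixed_guides = _downsample_side(self.fixed, self.fixed_guidance, n_levels)
        moving_imgs, moving_guides = _downsample_side(self.moving, self.moving_guidance, n_levels)

        init = pre_align(self.fixed, self.moving, self.fixed_guidance,
                         self.moving_guidance, scale=cfg.prealign_scale)
        # restrict the initial field to the coarsest grid
        field = prolong_displacement(init, fixed_imgs[-1].grid)

        traces, messages = [], []
        for level in range(n_levels - 1, -1, -1):  # coarse -> fine
            R_l, gR_l = fixed_imgs[level], fixed_guides[level]
            T_l, gT_l = moving_imgs[level], moving_guides[level]
            eps_l = resolve_edge_parameters(R_l, T_l, cfg)
            grid_l = R_l.grid
            shape_l = (*grid_l.shape, 3)

            def fun(x, R_l=R_l, T_l=T_l, gR_l=gR_l, gT_l=gT_l, eps_l=eps_l,
                    grid_l=grid_l, shape_l=shape_l):
                f = DisplacementField(grid_l, x.reshape(shape_l))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v, g = objective(R_l, T_l, f, gR_l, gT_l, cfg, eps=eps_l)
                if g is None:
                    return np.inf, None
                return v, g.ravel()

            max_iters = cfg.iters_for_level(n_levels - 1 - level, n_levels)
            x, trace, msgs = lbfgs(
                fun, field.u.ravel(), memory=cfg.lbfgs_memory, max_iters=max_iters,
                grad_tol_rel=cfg.grad_tol, armijo_c=cfg.armijo_c,
                max_backtracks=cfg.max_backtracks, step_cap=max(grid_l.spacing),
            )
            traces.append(trace)
            messages.extend(msgs)
            field = DisplacementField(grid_l, x.reshape(shape_l))
            log.info("level %d (%s): %d iters, J %.5g -> %.5g",
                     level, grid_l.shape, len(trace) - 1, trace[0], trace[-1])
            if level > 0:
                field = prolong_displacement(field, fixed_imgs[level - 1].grid)

        terms: dict = {}
        eps_f = resolve_edge_parameters(self.fixed, self.moving, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total, _ = objective(self.fixed, self.moving, field, self.fixed_guidance,
                                 self.moving_guidance, cfg, eps=eps_f, terms_out=terms)
        terms["total"] = total
        min_jac = float(jacobian_determinant(field).values.min())
        return RegistrationResult(
            field=field,
            objective_trace=traces,
            term_values=terms,
            min_jacobian=min_jac,
            converged=not messages,
            messages=messages,
        )


def register(R: ScalarVolume, T: ScalarVolume, guidance_R: GuidanceSet,
             guidance_T: GuidanceSet,
             config: RegistrationConfig | None = None) -> RegistrationResult:
    """Register a fixed/moving pair (functional wrapper over :class:`PairRegistration`)."""
    return PairRegistration(R, T, guidance_R, guidance_T, config).fit()
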