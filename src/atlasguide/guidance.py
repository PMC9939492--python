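"""Structure guidance: ventricle/parenchyma masks, centers of gravity, and
the mask-overlap and landmark penalty terms.

Inter-subject CT-MR registration driven by intensity alone often misaligns
the ventricles.  Guidance injects prior knowledge from segmentation masks of
the brain parenchyma (BP), left/right lateral ventricles (LLV, RLV) and
fourth ventricle (FV): a soft mask-overlap penalty pulls the warped moving
masks onto the fixed masks, and a landmark penalty matches the ventricles'
centers of gravity.  The COG need not lie inside its ventricle — it serves
as a robust reference point, not an anatomical landmark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as _dfield

import numpy as np

from .image_model import (
    DisplacementField,
    MaskVolume,
    displacement_at_points,
    trilinear_sample,
)

__all__ = [
    "STRUCTURES",
    "VENTRICLES",
    "GuidanceSet",
    "GuidanceWeights",
    "build_guidance_set",
    "combine_ventricle_masks",
    "center_of_gravity",
    "mask_penalty",
    "landmark_penalty",
]

log = logging.getLogger(__name__)

STRUCTURES = ("BP", "LLV", "RLV", "FV")
VENTRICLES = ("LLV", "RLV", "FV")


@dataclass(frozen=True)
class GuidanceWeights:
    """Non-negative weights for the mask (gamma) and landmark (delta) terms."""

    gamma: float = 10.0
    delta: float = 5.0

    def __post_init__(self):
        if self.gamma < 0 or self.delta < 0:
            raise ValueError("guidance weights must be non-negative")


@dataclass
class GuidanceSet:
    """Structure masks plus derived ventricle union and centers of gravity.

    ``cogs`` holds one 3-vector (mm) per non-empty ventricle; empty
    structures are omitted so pathological or coarse-level inputs degrade
    gracefully instead of aborting.
    """

    masks: dict
    ventricle_union: MaskVolume
    cogs: dict = _dfield(default_factory=dict)

    @property
    def grid(self):
        return self.ventricle_union.grid


def build_guidance_set(masks: dict) -> GuidanceSet:
    """Assemble a :class:`GuidanceSet` from per-structure masks.

    ``masks`` maps structure names (subset of BP/LLV/RLV/FV) to
    :class:`MaskVolume` on one shared grid.  Ventricle COGs are computed for
    non-empty ventricle masks only.
    """
    unknown = set(masks) - set(STRUCTURES)
    if unknown:
        raise ValueError(f"unknown structure names: {sorted(unknown)}")
    grids = {id(m.grid): m.grid for m in masks.values()}
    if len({(g.shape, g.spacing, g.origin) for g in grids.values()}) > 1:
        raise ValueError("all guidance masks must share one grid")
    vent = {name: masks[name] for name in VENTRICLES if name in masks}
    if not vent:
        raise ValueError("at least one ventricle mask is required")
    union = combine_ventricle_masks(vent)
    cogs = {}
    for name, m in vent.items():
        if m.n_foreground == 0:
            log.warning("ventricle mask %s is empty; its landmark is dropped", name)
            continue
        cogs[name] = center_of_gravity(m)
    return GuidanceSet(masks=dict(masks), ventricle_union=union, cogs=cogs)


def combine_ventricle_masks(masks: dict) -> MaskVolume:
    """Voxelwise union of the ventricle masks (clipped to {0, 1}).

    For disjoint structures this equals their arithmetic sum; union is the
    safe generalization when masks touch or overlap.
    """
    vols = list(masks.values())
    if not vols:
        raise ValueError("no masks to combine")
    grid = vols[0].grid
    for m in vols[1:]:
        if m.grid != grid:
            raise ValueError("ventricle masks must share one grid")
    out = np.zeros(grid.shape, dtype=np.uint8)
    for m in vols:
        out |= m.values
    return MaskVolume(grid, out)


def center_of_gravity(mask: MaskVolume) -> np.ndarray:
    """Unweighted centroid (mm) of the voxel centers with value 1."""
    if mask.n_foreground == 0:
        raise ValueError("center of gravity of an empty mask is undefined")
    idx = np.argwhere(mask.values == 1)
    world = mask.grid.index_to_world(idx)
    return world.mean(axis=0)


def mask_penalty(M_T_warped: np.ndarray, M_R: MaskVolume):
    """Soft overlap penalty ``1/2 * sum (M_T(y) - M_R)^2 * voxelVolume``.

    ``M_T_warped`` is the *linearly* interpolated (real-valued in [0, 1])
    warp of the moving binary mask: re-thresholding it would make the term
    piecewise constant in the displacement and kill its gradient.  Returns
    ``(value, gradient w.r.t. the warped-mask values)``.
    """
    M_T_warped = np.asarray(M_T_warped, dtype=float)
    if M_T_warped.shape != M_R.grid.shape:
        raise ValueError("warped mask and reference mask must share one grid")
    vol = M_R.grid.voxel_volume
    diff = M_T_warped - M_R.values
    value = 0.5 * float(np.sum(diff * diff)) * vol
    return value, diff * vol


def landmark_penalty(field: DisplacementField, r, t):
    """Landmark term ``1/2 * sum_l ||y(r_l) - t_l||^2`` and its gradient w.r.t. u.

    ``r`` are fixed-image reference points (mm) and ``t`` their moving-image
    correspondences; ``y(r_l)`` is evaluated by trilinear interpolation of
    the displacement.  An empty landmark list contributes zero.
    """
    r = np.atleast_2d(np.asarray(r, dtype=float)) if len(r) else np.zeros((0, 3))
    t = np.atleast_2d(np.asarray(t, dtype=float)) if len(t) else np.zeros((0, 3))
    if r.shape != t.shape:
        raise ValueError("landmark lists r and t must have matching shapes")
    grad = np.zeros_like(field.u)
    if r.shape[0] == 0:
        return 0.0, grad
    u_at_r = displacement_at_points(field, r)
    resid = r + u_at_r - t
    value = 0.5 * float(np.sum(resid * resid))

    # scatter d/du: trilinear weights of each landmark distribute its residual
    idx = field.grid.world_to_index(r)
    base = np.floor(idx).astype(np.int64)
    frac = idx - base
    shape = field.grid.shape
    for l_ in range(r.shape[0]):
        for c0 in (0, 1):
            for c1 in (0, 1):
                for c2 in (0, 1):
                    ii = (base[l_, 0] + c0, base[l_, 1] + c1, base[l_, 2] + c2)
                    if any(ii[a] < 0 or ii[a] >= shape[a] for a in range(3)):
                        continue
                    w = (
                        (frac[l_, 0] if c0 else 1 - frac[l_, 0])
                        * (frac[l_, 1] if c1 else 1 - frac[l_, 1])
                        * (frac[l_, 2] if c2 else 1 - frac[l_, 2])
                    )
                    grad[ii[0], ii[1], ii[2], :] += w * resid[l_]
    return value, grad


def matched_landmarks(guidance_R: GuidanceSet, guidance_T: GuidanceSet):
    """Pairs (r, t) of ventricle COGs present on both sides, in fixed order.

    Structures whose COG is missing on either side (empty mask) are omitted
    with a warning — degenerate phantoms and pathology must not abort the
    registration.
    """
    r, t = [], []
    for name in VENTRICLES:
        if name in guidance_R.cogs and name in guidance_T.cogs:
            r.append(guidance_R.cogs[name])
            t.append(guidance_T.cogs[name])
        elif name in guidance_R.cogs or name in guidance_T.cogs:
            warnings.warn(f"landmark {name} missing on one side; omitted", stacklevel=2)
    return np.asarray(r), np.asarray(t)


def warped_mask_values(mask: MaskVolume, field: DisplacementField):
    """Linearly interpolated moving-mask values and position derivative at y(x)."""
    points = field.deformed_points()
    idx = mask.grid.world_to_index(points)
    vals, didx = trilinear_sample(mask.values.astype(float), idx, with_gradient=True)
    return vals, didx / np.asarray(mask.grid.spacing)
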