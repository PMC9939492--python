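"""Normalized gradient fields (NGF) image similarity.

NGF compares local gradient *directions* rather than raw intensities, which
makes it suitable for CT-MR registration where the two modalities map the
same anatomy to unrelated intensity scales.  With the noise-augmented inner
product ``<a, b>_eps = a.b + eps`` and norm ``|a|_eps = sqrt(a.a + eps^2)``,
the distance is the midpoint-quadrature discretization of

    NGF(R, T) = 1/2 * integral over the domain of
        1 - ( <gradR, gradT>_{eps_R eps_T} / (|gradT|_{eps_T} |gradR|_{eps_R}) )^2

The edge parameters ``eps_R, eps_T`` damp the contribution of gradients at
the noise level: where the true gradient magnitude is well below eps the
ratio tends to 1 and the integrand to 0, so noise-only regions do not drive
the registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_model import ScalarVolume, spatial_gradient, _grad_axis_adjoint

__all__ = ["EdgeParameters", "ngf_distance", "estimate_edge_parameter"]

#: floor returned for constant images, intensity/mm
EDGE_PARAMETER_FLOOR = 1e-3


@dataclass(frozen=True)
class EdgeParameters:
    """Edge parameters (intensity/mm) controlling the influence of noise."""

    eps_R: float
    eps_T: float

    def __post_init__(self):
        if self.eps_R <= 0 or self.eps_T <= 0:
            raise ValueError("edge parameters must be strictly positive")


def ngf_distance(R: ScalarVolume, T_warped: ScalarVolume, eps: EdgeParameters):
    """NGF distance between a fixed image and an already-warped moving image.

    Returns ``(value, gradient)`` where the gradient is taken with respect to
    the per-voxel values of ``T_warped`` (the warp chain rule is applied by
    the caller).  The per-voxel integrand lies in [0, 1] by the augmented
    Cauchy-Schwarz inequality, so ``0 <= value <= |domain| / 2``.
    """
    if R.grid != T_warped.grid:
        raise ValueError("ngf_distance requires both volumes on the same grid")
    grid = R.grid
    vol = grid.voxel_volume

    gR = spatial_gradient(R)
    gT = spatial_gradient(T_warped)

    a = np.einsum("...k,...k->...", gR, gT) + eps.eps_R * eps.eps_T
    b2 = np.einsum("...k,...k->...", gT, gT) + eps.eps_T**2
    c2 = np.einsum("...k,...k->...", gR, gR) + eps.eps_R**2

    rho2 = a * a / (b2 * c2)
    value = 0.5 * float(np.sum(1.0 - rho2)) * vol

    # d/dgT of the per-voxel integrand, times the quadrature weight
    coeff = a / (b2 * c2)
    dphi_dgT = -coeff[..., None] * (gR - (a / b2)[..., None] * gT) * vol
    grad = np.zeros(grid.shape)
    for ax in range(3):
        grad += _grad_axis_adjoint(dphi_dgT[..., ax], ax, grid.spacing[ax])
    return value, grad


def estimate_edge_parameter(volume: ScalarVolume, fraction: float = 0.1) -> float:
    """Heuristic edge parameter: ``fraction`` times the mean gradient magnitude.

    A constant image has no edges to key on; it yields the declared floor
    value with a warning rather than a zero (edge parameters must stay
    strictly positive).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    g = spatial_gradient(volume)
    mean_mag = float(np.mean(np.sqrt(np.einsum("...k,...k->...", g, g))))
    est = fraction * mean_mag
    if est <= 0:
        warnings.warn(
            "constant volume has no gradient information; "
            f"using edge-parameter floor {EDGE_PARAMETER_FLOOR}",
            stacklevel=2,
        )
        return EDGE_PARAMETER_FLOOR
    return est
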