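"""Deformation regularizers: curvature smoothness and the volume-change barrier.

Two energies keep the estimated deformation anatomically plausible:

* **Curvature**: ``1/2 * sum_k ||Laplacian(y_k)||^2`` penalizes second
  derivatives of the deformation.  Since the Laplacian of the identity map
  vanishes, ``Laplacian(y_k) = Laplacian(u_k)`` and affine deformations are
  free of charge.
* **Volume penalty**: ``integral of psi(det grad y)`` with
  ``psi(t) = (t - 1)^2 / t`` for ``t > 0`` and ``psi(t) = +inf`` otherwise.
  Growth and shrinkage are penalized symmetrically (``psi(t) = psi(1/t)``)
  and the infinite barrier at ``t <= 0`` forbids folds: a monotone line
  search can never accept an iterate whose discrete deformation changes
  topology.
"""

from __future__ import annotations

import numpy as np

from .image_model import (
    DisplacementField,
    displacement_jacobian,
    laplacian,
    _det3,
    _cofactor3,
    _grad_axis_adjoint,
)

__all__ = ["psi", "volume_penalty", "curvature_energy", "RegularizerWeights"]

from dataclasses import dataclass


@dataclass(frozen=True)
class RegularizerWeights:
    """Non-negative weights for curvature (alpha) and volume penalty (beta)."""

    alpha: float = 40.0
    beta: float = 0.1

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("regularizer weights must be non-negative")


def psi(t):
    """Symmetric volume-change penalty ``(t-1)^2/t`` with an infinite barrier.

    Accepts scalars or arrays; returns ``(value, derivative)``.  For
    ``t <= 0`` the value is ``+inf`` and the derivative is 0 (never used:
    the line search rejects infinite objectives outright).
    """
    t = np.asarray(t, dtype=float)
    pos = t > 0
    safe = np.where(pos, t, 1.0)
    val = np.where(pos, (safe - 1.0) ** 2 / safe, np.inf)
    der = np.where(pos, 1.0 - 1.0 / safe**2, 0.0)
    if val.ndim == 0:
        return float(val), float(der)
    return val, der


def volume_penalty(field: DisplacementField):
    """``sum_x psi(det grad y(x)) * voxelVolume`` and its gradient w.r.t. ``u``.

    Returns ``(+inf, None)`` as soon as any voxel has a non-positive
    Jacobian determinant (a folded or degenerate cell).
    """
    grid = field.grid
    vol = grid.voxel_volume
    A = displacement_jacobian(field)
    A[..., 0, 0] += 1.0
    A[..., 1, 1] += 1.0
    A[..., 2, 2] += 1.0
    det = _det3(A)
    if np.any(det <= 0):
        return np.inf, None
    val_vox, der_vox = psi(det)
    value = float(np.sum(val_vox)) * vol
    # chain rule: dE/d(du_i/dx_j) = psi'(det) * cofactor_ij, then the
    # adjoint of the difference operator maps back to u_i
    C = _cofactor3(A)
    W = der_vox[..., None, None] * C * vol
    grad = np.zeros_like(field.u)
    for i in range(3):
        for j in range(3):
            grad[..., i] += _grad_axis_adjoint(W[..., i, j], j, grid.spacing[j])
    return value, grad


def curvature_energy(field: DisplacementField):
    """``1/2 * sum_k sum_x (Laplacian u_k)^2 * voxelVolume`` and its gradient.

    The replicate-edge Laplacian is a symmetric operator, so the gradient is
    simply ``voxelVolume * L(L u_k)`` per component.
    """
    grid = field.grid
    vol = grid.voxel_volume
    value = 0.0
    grad = np.empty_like(field.u)
    for k in range(3):
        Lu = laplacian(field.u[..., k], grid.spacing)
        value += 0.5 * float(np.sum(Lu * Lu)) * vol
        grad[..., k] = laplacian(Lu, grid.spacing) * vol
    return value, grad
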