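"""Core geometric types and discrete operators for deformable registration.

All volumes live on axis-aligned 3D lattices described by :class:`ImageGrid`
(shape in voxels, spacing and origin in millimetres).  World coordinates are
voxel-center coordinates: voxel index ``(i, j, k)`` sits at
``origin + index * spacing``.  Deformations are represented Eulerian-ly as a
displacement ``u`` stored on the *fixed* image's grid, with deformation
``y(x) = x + u(x)`` and pull-back warping
``output(x) = input(x + u(x))``.

The differential operators defined here are the discrete building blocks of
every energy term: first derivatives use central differences in the interior
and one-sided differences on boundary slices (exact for affine fields on the
whole grid); the component-wise Laplacian uses the 7-point stencil with
replicate-edge (zero-Neumann) boundaries, which makes it a symmetric linear
operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "MaskVolume",
    "LabelVolume",
    "DisplacementField",
    "warp",
    "spatial_gradient",
    "jacobian_determinant",
    "component_laplacian",
    "displacement_at_points",
    "trilinear_sample",
]


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of an axis-aligned 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of 3 int
        Number of voxels per axis.
    spacing : tuple of 3 float
        Voxel size per axis in mm (strictly positive).
    origin : tuple of 3 float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 components")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (the midpoint-quadrature weight)."""
        return float(np.prod(self.spacing))

    def world_coordinates(self) -> np.ndarray:
        """Array of shape ``(*shape, 3)`` with the world coordinate of every voxel center."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert world coordinates (mm) to continuous voxel-index coordinates."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the first/last voxel centers."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


def _check_values(grid: ImageGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"{name} values shape {values.shape} != grid shape {grid.shape}")
    return values


@dataclass
class ScalarVolume:
    """Real-valued intensity image on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = _check_values(self.grid, self.values, "ScalarVolume").astype(float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ScalarVolume values must be finite")


@dataclass
class MaskVolume:
    """Binary {0,1} structure mask on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self):
        vals = _check_values(self.grid, self.values, "MaskVolume")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("MaskVolume values must be binary {0, 1}")
        self.values = vals.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class LabelVolume:
    """Non-negative integer anatomical label map (0 = background)."""

    grid: ImageGrid
    values: np.ndarray
    alphabet: frozenset = _field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        vals = _check_values(self.grid, self.values, "LabelVolume")
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(vals)
            if not np.allclose(vals, rounded):
                raise ValueError("LabelVolume values must be integers")
            vals = rounded.astype(np.int32)
        if (vals < 0).any():
            raise ValueError("LabelVolume values must be non-negative")
        self.values = vals.astype(np.int32)
        present = frozenset(int(v) for v in np.unique(self.values))
        if self.alphabet is None:
            self.alphabet = present
        else:
            self.alphabet = frozenset(int(v) for v in self.alphabet)
            if not present <= self.alphabet:
                raise ValueError("LabelVolume contains labels outside the declared alphabet")


@dataclass
class DisplacementField:
    """Per-voxel displacement ``u`` in mm; deformation ``y(x) = x + u(x)``."""

    grid: ImageGrid
    u: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        if u.shape != (*self.grid.shape, 3):
            raise ValueError(f"u shape {u.shape} != {(*self.grid.shape, 3)}")
        if not np.all(np.isfinite(u)):
            raise ValueError("displacement must be finite")
        self.u = u

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "DisplacementField":
        return cls(grid, np.zeros((*grid.shape, 3)))

    def deformed_points(self) -> np.ndarray:
        """World coordinates y(x) = x + u(x) for every voxel, shape ``(*shape, 3)``."""
        return self.grid.world_coordinates() + self.u


# ---------------------------------------------------------------------------
# Interpolation


def trilinear_sample(
    values: np.ndarray,
    idx: np.ndarray,
    *,
    with_gradient: bool = False,
    fill: float = 0.0,
):
    """Trilinear interpolation of ``values`` at continuous index coordinates.

    Out-of-extent corners contribute the ``fill`` value, so the interpolant
    decays to ``fill`` across one voxel beyond the last voxel center.  When
    ``with_gradient`` is set, the exact derivative of the interpolant with
    respect to the (index-coordinate) sample position is also returned, which
    the energy gradients chain through.
    """
    idx = np.asarray(idx, dtype=float)
    base = np.floor(idx).astype(np.int64)
    frac = idx - base
    shape = values.shape

    out = np.zeros(idx.shape[:-1], dtype=float)
    grad = np.zeros_like(idx) if with_gradient else None

    for c0 in (0, 1):
        for c1 in (0, 1):
            for c2 in (0, 1):
                corner = (c0, c1, c2)
                ii = [base[..., a] + corner[a] for a in range(3)]
                inside = (
                    (ii[0] >= 0) & (ii[0] < shape[0])
                    & (ii[1] >= 0) & (ii[1] < shape[1])
                    & (ii[2] >= 0) & (ii[2] < shape[2])
                )
                gathered = values[
                    np.clip(ii[0], 0, shape[0] - 1),
                    np.clip(ii[1], 0, shape[1] - 1),
                    np.clip(ii[2], 0, shape[2] - 1),
                ]
                v = np.where(inside, gathered, fill)
                w_ax = [
                    frac[..., a] if corner[a] else 1.0 - frac[..., a] for a in range(3)
                ]
                out += w_ax[0] * w_ax[1] * w_ax[2] * v
                if with_gradient:
                    s = [1.0 if corner[a] else -1.0 for a in range(3)]
                    grad[..., 0] += s[0] * w_ax[1] * w_ax[2] * v
                    grad[..., 1] += w_ax[0] * s[1] * w_ax[2] * v
                    grad[..., 2] += w_ax[0] * w_ax[1] * s[2] * v
    if with_gradient:
        return out, grad
    return out


def warp(volume, field: DisplacementField, mode: str = "linear"):
    """Pull-back warp of a volume by a displacement field.

    The output lives on ``field.grid``; the value at voxel center ``x`` is the
    input volume interpolated at ``y(x) = x + u(x)`` in the input's world
    frame.  Samples outside the input extent take the fill value 0
    (background for labels).  Label and mask volumes require ``nearest``.
    """
    if not np.all(np.isfinite(field.u)):
        raise ValueError("non-finite displacement")
    is_label = isinstance(volume, LabelVolume)
    is_mask = isinstance(volume, MaskVolume)
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "linear" and is_label:
        raise ValueError("linear interpolation is not defined for label volumes; use nearest")

    points = field.deformed_points()
    idx = volume.grid.world_to_index(points)
    # snap to the lattice where world->index roundoff would otherwise break
    # the exact-identity property of a zero displacement
    snapped = np.rint(idx)
    idx = np.where(np.abs(idx - snapped) < 1e-9, snapped, idx)
    vals = np.asarray(volume.values)

    if mode == "nearest":
        near = np.rint(idx).astype(np.int64)
        inside = np.all((near >= 0) & (near < np.asarray(vals.shape)), axis=-1)
        gathered = vals[
            np.clip(near[..., 0], 0, vals.shape[0] - 1),
            np.clip(near[..., 1], 0, vals.shape[1] - 1),
            np.clip(near[..., 2], 0, vals.shape[2] - 1),
        ]
        out = np.where(inside, gathered, np.asarray(0, dtype=vals.dtype))
    else:
        out = trilinear_sample(vals.astype(float), idx)

    if is_label:
        return LabelVolume(field.grid, out, alphabet=volume.alphabet)
    if is_mask:
        return MaskVolume(field.grid, out)
    return ScalarVolume(field.grid, out)


def displacement_at_points(field: DisplacementField, points) -> np.ndarray:
    """Trilinear interpolation of ``u`` at world points (mm), shape ``(n, 3)``.

    Points must lie inside the grid's voxel-center extent.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = field.grid.extent()
    if ((points < lo - 1e-9) | (points > hi + 1e-9)).any():
        raise ValueError("point outside the grid's world extent")
    idx = field.grid.world_to_index(points)
    out = np.empty_like(points)
    for k in range(3):
        out[:, k] = trilinear_sample(field.u[..., k], idx)
    return out


# ---------------------------------------------------------------------------
# Discrete differential operators


def _grad_axis(v: np.ndarray, axis: int, h: float) -> np.ndarray:
    """First derivative along one axis: central interior, one-sided boundaries."""
    n = v.shape[axis]
    if n == 1:
        return np.zeros_like(v)
    return np.gradient(v, h, axis=axis, edge_order=1)


def _grad_axis_adjoint(w: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Adjoint (transpose) of :func:`_grad_axis` as a linear operator."""
    n = w.shape[axis]
    if n == 1:
        return np.zeros_like(w)
    w = np.moveaxis(w, axis, 0)
    z = np.zeros_like(w)
    if n == 2:
        z[0] = (-w[0] - w[1]) / h
        z[1] = (w[0] + w[1]) / h
    else:
        # central rows 1..n-2 scatter to neighbours
        z[0:n - 2] += -w[1:n - 1] / (2 * h)
        z[2:n] += w[1:n - 1] / (2 * h)
        # one-sided boundary rows
        z[0] += -w[0] / h
        z[1] += w[0] / h
        z[n - 2] += -w[n - 1] / h
        z[n - 1] += w[n - 1] / h
    return np.moveaxis(z, 0, axis)


def spatial_gradient(volume: ScalarVolume) -> np.ndarray:
    """Spacing-aware gradient of an intensity image, shape ``(*shape, 3)``, intensity/mm.

    Central differences in the interior, one-sided on boundary slices; a
    degenerate (length-1) axis yields a zero component.
    """
    g = np.empty((*volume.grid.shape, 3))
    for a in range(3):
        g[..., a] = _grad_axis(volume.values, a, volume.grid.spacing[a])
    return g


def displacement_jacobian(field: DisplacementField) -> np.ndarray:
    """Matrix field ``(∇u)_{ij} = ∂u_i/∂x_j`` with shape ``(*shape, 3, 3)``."""
    G = np.empty((*field.grid.shape, 3, 3))
    for i in range(3):
        for j in range(3):
            G[..., i, j] = _grad_axis(field.u[..., i], j, field.grid.spacing[j])
    return G


def _det3(A: np.ndarray) -> np.ndarray:
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _cofactor3(A: np.ndarray) -> np.ndarray:
    """Cofactor matrix C with C_ij = d det(A) / d A_ij."""
    C = np.empty_like(A)
    C[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    C[..., 0, 1] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    C[..., 0, 2] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    C[..., 1, 0] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    C[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    C[..., 1, 2] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    C[..., 2, 0] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    C[..., 2, 1] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    C[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return C


def jacobian_determinant(field: DisplacementField) -> ScalarVolume:
    """det ∇y per voxel with ∇y = I + ∇u (dimensionless volume-change factor)."""
    A = displacement_jacobian(field)
    A[..., 0, 0] += 1.0
    A[..., 1, 1] += 1.0
    A[..., 2, 2] += 1.0
    return ScalarVolume(field.grid, _det3(A))


def _laplace_axis(v: np.ndarray, axis: int, h: float) -> np.ndarray:
    """1D second-difference with replicate-edge (zero-Neumann) boundary; symmetric."""
    n = v.shape[axis]
    if n == 1:
        return np.zeros_like(v)
    v = np.moveaxis(v, axis, 0)
    out = np.empty_like(v)
    out[1:n - 1] = v[0:n - 2] - 2 * v[1:n - 1] + v[2:n]
    out[0] = v[1] - v[0]
    out[n - 1] = v[n - 2] - v[n - 1]
    return np.moveaxis(out, 0, axis) / (h * h)


def laplacian(values: np.ndarray, spacing) -> np.ndarray:
    """7-point discrete Laplacian of a scalar array, replicate-edge boundaries."""
    return sum(_laplace_axis(values, a, spacing[a]) for a in range(3))


def component_laplacian(field: DisplacementField) -> np.ndarray:
    """Δu per displacement component, shape ``(*shape, 3)`` (1/mm)."""
    out = np.empty_like(field.u)
    for k in range(3):
        out[..., k] = laplacian(field.u[..., k], field.grid.spacing)
    return out
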