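"""Synthetic two-modality brain phantoms with known ground-truth deformations.

The generator produces an ellipsoidal "brain" containing a mirrored pair of
lateral ventricles and a small fourth ventricle, rendered twice from the same
geometry: a CT-like mapping (bright skull shell, mid-gray parenchyma, dark
ventricles) and an MR-like mapping with partially inverted contrast (dark
shell, bright CSF).  Per-structure binary masks, an anatomical label map
with extra parenchyma parcels, and smooth invertible random deformations
provide everything the registration, guidance and multi-atlas machinery
needs for fully self-contained experiments.

Everything is a deterministic function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_model import (
    DisplacementField,
    ImageGrid,
    LabelVolume,
    MaskVolume,
    ScalarVolume,
    jacobian_determinant,
    warp,
)
from .guidance import GuidanceSet, build_guidance_set

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "random_subject_spec",
    "random_smooth_field",
    "deform_phantom",
]

#: label ids of the guidance structures in phantom label maps
LABEL_IDS = {"BP": 1, "LLV": 2, "RLV": 3, "FV": 4}
VENTRICLE_LABEL_IDS = frozenset({2, 3, 4})

# piecewise-constant intensity mappings per structure; the parcel values
# emulate the gray/white-matter and deep-nuclei contrast a real atlas has,
# giving the similarity term interior edges in both modalities
_CT_INTENSITY = {"bg": 0.0, "shell": 1.0, "tissue": 0.55, "ventricle": 0.15,
                 "parcels": (0.66, 0.44, 0.70, 0.40, 0.63, 0.47, 0.68, 0.42)}
_MR_INTENSITY = {"bg": 0.0, "shell": 0.08, "tissue": 0.45, "ventricle": 0.9,
                 "parcels": (0.30, 0.62, 0.25, 0.68, 0.33, 0.58, 0.28, 0.65)}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of one phantom (mm).

    Offsets are relative to the brain center; the right lateral ventricle
    mirrors the left across the mid-sagittal (x) plane by default, so the
    default phantom is exactly mirror symmetric.
    """

    shape: tuple = (48, 48, 48)
    spacing: tuple = (1.0, 1.0, 1.0)
    brain_semiaxes: tuple = (19.0, 21.0, 17.0)
    llv_semiaxes: tuple = (4.5, 8.0, 5.5)
    llv_offset: tuple = (7.5, 1.5, 2.5)
    rlv_semiaxes: tuple = None  # type: ignore[assignment]
    rlv_offset: tuple = None  # type: ignore[assignment]
    fv_semiaxes: tuple = (2.5, 3.5, 2.5)
    fv_offset: tuple = (0.0, -9.0, -7.0)
    shell_thickness: float = 2.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.rlv_semiaxes is None:
            object.__setattr__(self, "rlv_semiaxes", tuple(self.llv_semiaxes))
        if self.rlv_offset is None:
            mirrored = (-self.llv_offset[0], self.llv_offset[1], self.llv_offset[2])
            object.__setattr__(self, "rlv_offset", mirrored)
        for ax in (self.brain_semiaxes, self.llv_semiaxes, self.rlv_semiaxes, self.fv_semiaxes):
            if any(a <= 0 for a in ax):
                raise ValueError("semi-axes must be positive")


@dataclass
class Phantom:
    """One synthetic subject: both modality renderings, guidance, labels."""

    ct: ScalarVolume
    mr: ScalarVolume
    guidance: GuidanceSet
    labels: LabelVolume
    spec: PhantomSpec
    ground_truth_field: DisplacementField = _dfield(default=None)  # type: ignore[assignment]

    @property
    def grid(self) -> ImageGrid:
        return self.ct.grid


def _ellipsoid(grid: ImageGrid, center, semiaxes) -> np.ndarray:
    x = grid.world_coordinates()
    q = sum(((x[..., a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    return q <= 1.0


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the phantom described by ``spec``.

    Raises if any ventricle pokes outside the brain ellipsoid, which would
    break the mask/label consistency invariants.
    """
    grid = ImageGrid(spec.shape, spec.spacing)
    lo, hi = grid.extent()
    center = (np.asarray(lo) + np.asarray(hi)) / 2.0

    brain = _ellipsoid(grid, center, spec.brain_semiaxes)
    shell = _ellipsoid(
        grid, center, tuple(a + spec.shell_thickness for a in spec.brain_semiaxes)
    ) & ~brain
    llv = _ellipsoid(grid, center + np.asarray(spec.llv_offset), spec.llv_semiaxes)
    rlv = _ellipsoid(grid, center + np.asarray(spec.rlv_offset), spec.rlv_semiaxes)
    fv = _ellipsoid(grid, center + np.asarray(spec.fv_offset), spec.fv_semiaxes)

    for name, m in (("LLV", llv), ("RLV", rlv), ("FV", fv)):
        if np.any(m & ~brain):
            raise ValueError(f"ventricle {name} extends outside the brain ellipsoid")

    ventricles = llv | rlv | fv
    tissue = brain & ~ventricles

    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[tissue] = LABEL_IDS["BP"]
    labels[llv] = LABEL_IDS["LLV"]
    labels[rlv] = LABEL_IDS["RLV"]
    labels[fv] = LABEL_IDS["FV"]
    # extra parenchyma parcels emulating a fuller anatomical atlas
    parcel_defs = [
        ((10.0, -8.0, -2.0), (4.5, 4.5, 4.5)),
        ((-10.0, -8.0, -2.0), (4.5, 4.5, 4.5)),
        ((0.0, 11.0, -3.0), (4.5, 5.5, 4.5)),
        ((0.0, -3.0, 9.5), (5.0, 4.5, 4.0)),
        ((8.0, 9.0, 6.0), (3.5, 4.0, 3.5)),
        ((-8.0, 9.0, 6.0), (3.5, 4.0, 3.5)),
        ((6.5, -13.0, 5.0), (3.5, 3.5, 3.5)),
        ((-6.5, -13.0, 5.0), (3.5, 3.5, 3.5)),
    ]
    parcel_masks = []
    for p, (off, semi) in enumerate(parcel_defs):
        parcel = _ellipsoid(grid, center + np.asarray(off), semi) & tissue
        labels[parcel] = 5 + p
        parcel_masks.append(parcel)

    rng = np.random.default_rng(spec.seed)

    def render(mapping):
        img = np.full(grid.shape, mapping["bg"])
        img[shell] = mapping["shell"]
        img[tissue] = mapping["tissue"]
        img[ventricles] = mapping["ventricle"]
        for p in range(len(parcel_defs)):
            img[labels == 5 + p] = mapping["parcels"][p]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, grid.shape)
        return ScalarVolume(grid, img)

    ct = render(_CT_INTENSITY)
    mr = render(_MR_INTENSITY)

    masks = {
        "BP": MaskVolume(grid, brain.astype(np.uint8)),
        "LLV": MaskVolume(grid, llv.astype(np.uint8)),
        "RLV": MaskVolume(grid, rlv.astype(np.uint8)),
        "FV": MaskVolume(grid, fv.astype(np.uint8)),
    }
    return Phantom(
        ct=ct,
        mr=mr,
        guidance=build_guidance_set(masks),
        labels=LabelVolume(grid, labels),
        spec=spec,
    )


def random_subject_spec(seed: int, base: PhantomSpec | None = None,
                        variability: float = 1.0) -> PhantomSpec:
    """Draw a subject-specific anatomy emulating inter-subject variability.

    Brain size, ventricle positions and — most importantly — ventricle sizes
    vary between subjects; ventricular enlargement is common in clinical CT
    cohorts, so ventricle semi-axes are scaled by a factor drawn from
    [0.85, 1.45] (shared by both lateral ventricles to keep anatomy
    plausible).  The mid-sagittal mirror symmetry of the template is broken
    by independent left/right offset jitter.  ``variability`` scales every
    deviation from the template: 1 emulates a general clinical cohort, small
    values the near-template subjects an atlas-bootstrap pool is drawn from.
    """
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    v = float(variability)
    brain = tuple(a + v * rng.uniform(-1.5, 1.5) for a in base.brain_semiaxes)
    vscale = 1.0 + v * rng.uniform(-0.15, 0.45)
    jit = lambda: v * rng.uniform(-1.2, 1.2)
    llv_off = (base.llv_offset[0] + jit(), base.llv_offset[1] + jit(),
               base.llv_offset[2] + jit())
    rlv_off = (-base.llv_offset[0] + jit(), base.llv_offset[1] + jit(),
               base.llv_offset[2] + jit())
    return PhantomSpec(
        shape=base.shape,
        spacing=base.spacing,
        brain_semiaxes=brain,
        llv_semiaxes=tuple(a * vscale for a in base.llv_semiaxes),
        llv_offset=llv_off,
        rlv_semiaxes=tuple(a * vscale for a in base.llv_semiaxes),
        rlv_offset=rlv_off,
        fv_semiaxes=tuple(a * (1.0 + v * rng.uniform(-0.15, 0.25))
                          for a in base.fv_semiaxes),
        fv_offset=(base.fv_offset[0] + 0.5 * jit(), base.fv_offset[1] + jit(),
                   base.fv_offset[2] + jit()),
        shell_thickness=base.shell_thickness,
        noise_sd=base.noise_sd,
        seed=seed,
    )


def random_smooth_field(grid: ImageGrid, amplitude: float, smoothness: float,
                        seed: int) -> DisplacementField:
    """Gaussian-smoothed random displacement with a guaranteed Jacobian floor.

    White noise per component is smoothed with kernel width ``smoothness``
    (mm) and rescaled so the largest displacement magnitude equals
    ``amplitude`` (mm).  Candidates are redrawn (continuing the same seeded
    stream) until ``min det grad y > 0.2``, keeping ground-truth recovery
    problems well posed under the fold barrier.
    """
    if amplitude < 0 or smoothness <= 0:
        raise ValueError("amplitude must be >= 0 and smoothness > 0")
    if amplitude == 0:
        return DisplacementField.zeros(grid)
    rng = np.random.default_rng(seed)
    sigma = [smoothness / s for s in grid.spacing]
    for _ in range(20):
        u = rng.standard_normal((*grid.shape, 3))
        for k in range(3):
            # periodic smoothing keeps the field statistically stationary;
            # edge-replicating modes inflate boundary variance and would let
            # the max-rescaling be dominated by corner artifacts
            u[..., k] = gaussian_filter(u[..., k], sigma=sigma, mode="wrap")
        mag = np.sqrt(np.einsum("...k,...k->...", u, u))
        u *= amplitude / mag.max()
        field = DisplacementField(grid, u)
        if jacobian_determinant(field).values.min() > 0.2:
            return field
    raise ValueError(
        "could not draw a field with min det(grad y) > 0.2 in 20 attempts; "
        "lower the amplitude or increase the smoothness"
    )


def deform_phantom(phantom: Phantom, field: DisplacementField) -> Phantom:
    """Warp a phantom by ``field`` (pull-back), keeping the field as ground truth.

    Intensities are interpolated linearly, masks and labels with nearest
    neighbors, so mask/label consistency is preserved.  Folding fields are
    rejected.
    """
    det_min = jacobian_determinant(field).values.min()
    if det_min <= 0:
        raise ValueError(f"deformation folds (min det = {det_min:.3g})")
    ct = warp(phantom.ct, field, mode="linear")
    mr = warp(phantom.mr, field, mode="linear")
    labels = warp(phantom.labels, field, mode="nearest")
    masks = {k: warp(m, field, mode="nearest") for k, m in phantom.guidance.masks.items()}
    return Phantom(
        ct=ct,
        mr=mr,
        guidance=build_guidance_set(masks),
        labels=labels,
        spec=phantom.spec,
        ground_truth_field=field,
    )
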