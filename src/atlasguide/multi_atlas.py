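"""Bootstrapped multi-modal multi-atlas label propagation.

A single MR atlas (intensity template + anatomical labels + guidance) is
*bootstrapped* into a multi-modal atlas set: CT images are registered to the
MR atlas, receive propagated labels, and those whose ventricle Dice against
their own guidance masks clears a quality threshold are promoted to CT
atlases.  A new target is then registered to every atlas independently and
the warped label image of the atlas with the highest ventricle Dice is
selected globally; per-voxel majority voting is available as an alternative
fusion rule but is off by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .image_model import LabelVolume, MaskVolume, ScalarVolume, warp
from .guidance import GuidanceSet
from .metrics import dice
from .registration import PairRegistration, RegistrationConfig

__all__ = [
    "Atlas",
    "AtlasSet",
    "propagate",
    "select_best",
    "bootstrap_atlases",
    "majority_vote",
    "multi_atlas_labels",
]

log = logging.getLogger(__name__)


@dataclass
class Atlas:
    """Intensity template with aligned anatomical labels and guidance masks."""

    intensity: ScalarVolume
    labels: LabelVolume
    guidance: GuidanceSet
    modality_tag: str = "MR-like"
    id: str = "atlas"

    def __post_init__(self):
        if self.intensity.grid != self.labels.grid:
            raise ValueError("atlas labels and intensity must share a grid")


@dataclass
class AtlasSet:
    """Ordered atlases: the MR-like seed first, bootstrapped CT-like members after."""

    atlases: list

    def __post_init__(self):
        if not self.atlases:
            raise ValueError("AtlasSet must be non-empty")
        ids = [a.id for a in self.atlases]
        if len(set(ids)) != len(ids):
            raise ValueError("atlas ids must be unique")

    def __iter__(self):
        return iter(self.atlases)

    def __len__(self):
        return len(self.atlases)


def propagate(atlas: Atlas, target: ScalarVolume, target_guidance: GuidanceSet,
              config: RegistrationConfig | None = None):
    """Register ``target`` (fixed) to the atlas (moving) and warp the atlas labels.

    Returns ``(labels, result)`` with the propagated :class:`LabelVolume` on
    the target grid and the underlying :class:`RegistrationResult`.
    """
    result = PairRegistration(
        target, atlas.intensity, target_guidance, atlas.guidance, config
    ).fit()
    labels = warp(atlas.labels, result.field, mode="nearest")
    return labels, result


def _ventricle_mask(labels: LabelVolume, ventricle_label_ids) -> MaskVolume:
    return MaskVolume(
        labels.grid, np.isin(labels.values, list(ventricle_label_ids)).astype(np.uint8)
    )


def select_best(candidates, target_ventricle_mask: MaskVolume, ventricle_label_ids):
    """Global selection: the candidate label image with the highest ventricle Dice.

    ``candidates`` is a list of ``(LabelVolume, atlas_id)``; the ventricle
    mask of each candidate (union of ``ventricle_label_ids``) is compared to
    the target's ventricle mask.  Ties break toward the earliest atlas.
    Returns ``(labels, atlas_id, dice)``.
    """
    if not candidates:
        raise ValueError("select_best requires at least one candidate")
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for labels, _aid in candidates:
            scores.append(dice(_ventricle_mask(labels, ventricle_label_ids),
                               target_ventricle_mask))
    best = int(np.argmax(scores))  # argmax returns the first maximum: earliest atlas wins
    labels, aid = candidates[best]
    return labels, aid, float(scores[best])


def bootstrap_atlases(mr_atlas: Atlas, ct_pool, k: int, dice_threshold: float = 0.94,
                      config: RegistrationConfig | None = None) -> AtlasSet:
    """Promote the best-registered CT images of a pool to auxiliary atlases.

    Every ``(intensity, guidance)`` pool member is registered to the MR
    atlas and receives propagated labels; members are ranked by the
    ventricle Dice between those labels and their own ventricle guidance
    mask.  The top ``k`` at or above ``dice_threshold`` (default 0.94)
    become CT-like atlases; if fewer pass, all passing members are promoted
    with a warning.
    """
    if len(ct_pool) < k:
        raise ValueError("ct_pool must contain at least k members")
    scored = []
    for i, (intensity, guidance) in enumerate(ct_pool):
        labels, result = propagate(mr_atlas, intensity, guidance, config)
        vm = _ventricle_mask(labels, _ventricle_ids_of(mr_atlas))
        d = dice(vm, guidance.ventricle_union)
        log.info("bootstrap candidate %d: ventricle Dice %.4f", i, d)
        scored.append((d, i, intensity, guidance, labels))
    passing = [s for s in scored if s[0] >= dice_threshold]
    # stable sort by descending Dice; ties keep pool order
    passing.sort(key=lambda s: (-s[0], s[1]))
    if len(passing) < k:
        warnings.warn(
            f"only {len(passing)} of {len(ct_pool)} pool members reached "
            f"ventricle Dice >= {dice_threshold}; promoting those",
            stacklevel=2,
        )
    promoted = [
        Atlas(intensity=intensity, labels=labels, guidance=guidance,
              modality_tag="CT-like", id=f"ct{i}")
        for _d, i, intensity, guidance, labels in passing[:k]
    ]
    return AtlasSet([mr_atlas] + promoted)


def _ventricle_ids_of(atlas: Atlas):
    """Label ids of the ventricle structures in an atlas label map (ids 2, 3, 4)."""
    from .synthetic import VENTRICLE_LABEL_IDS

    return set(VENTRICLE_LABEL_IDS) & atlas.labels.alphabet or set(VENTRICLE_LABEL_IDS)


def multi_atlas_labels(atlas_set: AtlasSet, target: ScalarVolume,
                       target_guidance: GuidanceSet, ventricle_label_ids,
                       config: RegistrationConfig | None = None):
    """Full multi-atlas pipeline for one target.

    Registers the target to every atlas, then selects globally by ventricle
    Dice.  Returns ``(labels, atlas_id, dice, per_atlas)`` where
    ``per_atlas`` lists ``(atlas_id, dice)`` in atlas order.
    """
    candidates = []
    per_atlas = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for atlas in atlas_set:
            labels, _res = propagate(atlas, target, target_guidance, config)
            candidates.append((labels, atlas.id))
            d = dice(_ventricle_mask(labels, ventricle_label_ids),
                     target_guidance.ventricle_union)
            per_atlas.append((atlas.id, float(d)))
    labels, aid, best = select_best(candidates, target_guidance.ventricle_union,
                                    ventricle_label_ids)
    return labels, aid, best, per_atlas


def majority_vote(candidates) -> LabelVolume:
    """Per-voxel modal label across candidate label images (ties: lowest id)."""
    if not candidates:
        raise ValueError("majority_vote requires at least one candidate")
    grid = candidates[0].grid
    for c in candidates[1:]:
        if c.grid != grid:
            raise ValueError("majority_vote requires a shared grid")
    stack = np.stack([c.values for c in candidates])
    alphabet = np.unique(stack)
    counts = np.stack([(stack == lab).sum(axis=0) for lab in alphabet])
    # argmax over the first axis picks the first (lowest) label on ties
    winner = alphabet[np.argmax(counts, axis=0)]
    return LabelVolume(grid, winner)
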