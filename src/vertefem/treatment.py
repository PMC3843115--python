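"""Parametric treatment operators.

Each operator takes a model (and where needed its label map) and returns a
modified copy, touching only its targeted label set:

* :func:`apply_augmentation` — cement regions take the cement modulus,
  optionally reduced to represent a bone-cement composite stiffer than the
  surrounding bone but softer than pure cement,
* :func:`vary_cement_volume` — grow or shrink the augmented region by a
  deterministic distance-ordered re-labelling, restoring the exact
  greyscale-derived modulus of any element that leaves the region,
* :func:`scale_bone_quality` — multiply every element-specific bone modulus
  by a factor (osteoporotic vs dense bone),
* :func:`set_disc_state` — swap annulus and nucleus between reference
  healthy and degenerated property sets (or supplied ones, e.g. the
  calibrated state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import LabelMap, LEVELS, cement_label, trabecular_label, vertebra_labels
from .fe_core import Model
from .materials import BONE_POISSON, Material

__all__ = [
    "TreatmentConfig",
    "apply_augmentation",
    "vary_cement_volume",
    "scale_bone_quality",
    "set_disc_state",
    "PURE_CEMENT_E",
]

#: elastic modulus of pure injected cement, MPa
PURE_CEMENT_E = 2040.0
_CEMENT_POISSON = 0.3


@dataclass(frozen=True)
class TreatmentConfig:
    """One cell of the parametric treatment space.

    ``cement_modulus_fraction`` spans pure cement (1.0) down to composite
    estimates (0.5, 0.25, 0.125); ``volume_factor`` multiplies the base
    fill fraction; ``bone_factor`` multiplies every bone element modulus;
    ``disc_state`` selects the disc property set.
    """

    augmented_levels: tuple[str, ...] = ("L1",)
    cement_E: float = PURE_CEMENT_E
    cement_modulus_fraction: float = 1.0
    fill_fraction: float = 0.2
    volume_factor: float = 1.0
    bone_factor: float = 1.0
    disc_state: str = "degenerated"
    label: str = ""

    def __post_init__(self) -> None:
        for lv in self.augmented_levels:
            if lv not in LEVELS:
                raise ValueError(f"unknown level {lv!r}")
        if self.cement_E <= 0 or self.cement_modulus_fraction <= 0:
            raise ValueError("cement modulus must be positive")
        if not 0 < self.fill_fraction <= 1:
            raise ValueError("fill_fraction must lie in (0, 1]")
        if self.volume_factor <= 0 or self.bone_factor <= 0:
            raise ValueError("volume and bone factors must be positive")
        if self.disc_state not in ("healthy", "degenerated"):
            raise ValueError("disc_state must be 'healthy' or 'degenerated'")

    @property
    def effective_cement_E(self) -> float:
        return self.cement_E * self.cement_modulus_fraction

    def describe(self) -> str:
        if self.label:
            return self.label
        lv = "+".join(self.augmented_levels) or "none"
        return (
            f"levels={lv},cemE={self.effective_cement_E:g},"
            f"vol={self.volume_factor:g},bone={self.bone_factor:g},disc={self.disc_state}"
        )


def apply_augmentation(
    model: Model, levels: tuple[str, ...], cement_E: float = PURE_CEMENT_E
) -> Model:
    """Assign the cement material to the cement regions of ``levels``.

    The augmented-region modulus *replaces* the underlying bone modulus —
    composite behaviour is represented by the caller passing a reduced
    ``cement_E``, not by blending.  Elements outside the named regions are
    untouched.  Levels not present as cement regions raise.
    """
    out = model.copy()
    for lv in levels:
        mask = out.element_mask(f"cement_{lv}")
        if not mask.any():
            raise ValueError(f"no cement region exists at level {lv}")
        out.elem_E[mask] = cement_E
        out.elem_nu[mask] = _CEMENT_POISSON
        out.augmented[lv] = cement_E
    return out


def vary_cement_volume(
    model: Model, labels: LabelMap, level: str, volume_factor: float
) -> tuple[Model, LabelMap]:
    """Grow or shrink a cement region to ``volume_factor`` times its count.

    The region is re-derived by the same deterministic distance-from-
    centroid ordering that seeded it, so regions at different volumes are
    nested and the achieved count is exact (bounded by the trabecular
    volume).  Elements that leave the region recover their greyscale-
    derived modulus bit-exactly; elements that join take the model's
    current cement modulus if the level is augmented, otherwise they keep
    carrying bone properties.
    """
    if volume_factor <= 0:
        raise ValueError("volume_factor must be positive")
    clab = cement_label(level)
    cem = labels.mask(clab)
    n0 = int(cem.sum())
    if n0 == 0:
        raise ValueError(f"no cement region exists at level {level}")
    trab = labels.mask(trabecular_label(level))
    target = int(round(volume_factor * n0))
    avail = n0 + int(trab.sum())
    if target > avail:
        raise ValueError(
            f"requested cement volume ({target} elements) exceeds the vertebral "
            f"body's capacity; at most {avail} elements ({avail / n0:.2f}x) fit"
        )

    pool = np.argwhere(cem | trab)
    body = labels.mask(*vertebra_labels(level))
    centroid = np.argwhere(body).mean(axis=0)
    d2 = ((pool - centroid) ** 2).sum(axis=1)
    order = np.lexsort((pool[:, 2], pool[:, 1], pool[:, 0], d2))
    chosen = pool[order[:target]]

    new_labels = labels.copy()
    new_labels.data[cem | trab] = trabecular_label(level)
    new_labels.data[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = clab

    out = model.copy()
    vox = out.elem_voxel
    new_cem_elem = new_labels.data[vox[:, 0], vox[:, 1], vox[:, 2]] == clab
    old_cem_elem = out.element_mask(f"cement_{level}")
    out.elem_label = new_labels.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    left = old_cem_elem & ~new_cem_elem
    out.elem_E[left] = out.base_bone_E[left]
    out.elem_nu[left] = BONE_POISSON
    if level in out.augmented:
        out.elem_E[new_cem_elem] = out.augmented[level]
        out.elem_nu[new_cem_elem] = _CEMENT_POISSON
    else:
        joined = new_cem_elem & ~old_cem_elem
        out.elem_E[joined] = out.base_bone_E[joined]
    out.labels = new_labels
    return out, new_labels


def scale_bone_quality(model: Model, bone_factor: float) -> Model:
    """Multiply every element-specific bone modulus by ``bone_factor``.

    Applies to trabecular and cortical elements of every level, and to
    cement-labelled elements that still carry bone properties (i.e. the
    level is not yet augmented).  Cement, disc and housing moduli are
    untouched.  The stored base bone moduli are scaled too, so later
    restores reflect the chosen bone quality.
    """
    if bone_factor <= 0:
        raise ValueError("bone_factor must be positive")
    out = model.copy()
    bone = np.zeros(out.n_elements, bool)
    for lv in LEVELS:
        bone |= out.element_mask(f"trabecular_{lv}", f"cortical_{lv}")
        if lv not in out.augmented:
            bone |= out.element_mask(f"cement_{lv}")
    out.elem_E[bone] *= bone_factor
    out.base_bone_E *= bone_factor
    return out


def set_disc_state(
    model: Model,
    state: str,
    healthy: "tuple[Material, Material] | None" = None,
    degenerated: "tuple[Material, Material] | None" = None,
) -> Model:
    """Assign the annulus/nucleus property set for ``state``.

    ``healthy``/``degenerated`` override the reference sets with
    ``(annulus, nucleus)`` pairs — e.g. pass the calibrated pair as the
    degenerated state.  Switching is exactly invertible.
    """
    from .materials import (
        degenerated_annulus,
        degenerated_nucleus,
        healthy_annulus,
        healthy_nucleus,
    )

    if state == "healthy":
        ann, nuc = healthy if healthy is not None else (healthy_annulus(), healthy_nucleus())
    elif state == "degenerated":
        ann, nuc = (
            degenerated
            if degenerated is not None
            else (degenerated_annulus(), degenerated_nucleus())
        )
    else:
        raise ValueError("state must be 'healthy' or 'degenerated'")
    out = model.copy()
    out.annulus = ann
    nmask = out.element_mask("nucleus_upper", "nucleus_lower")
    out.elem_E[nmask] = nuc.E
    out.elem_nu[nmask] = nuc.nu
    return out
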