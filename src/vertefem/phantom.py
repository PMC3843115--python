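"""Synthetic three-vertebra phantom generator.

Real quantitative-CT scans of cadaveric spine segments are not distributable,
so the pipeline is exercised on a synthetic stand-in: a T12-L1-L2 stack of
elliptic-cylinder vertebral bodies separated by two disc slabs (an annulus
ring enclosing a nucleus core), capped by potting housings at both ends.
Trabecular bone carries an i.i.d. Gaussian greyscale field clipped at zero;
all other tissues carry constant greyscale values, which makes the phantom
exactly recoverable by threshold segmentation.

The default trabecular greyscale parameters are chosen so that, after zero
clipping and the default linear greyscale-to-modulus calibration, the mapped
modulus has population mean 128.41 MPa and standard deviation 66.20 MPa —
the element-specific bone-modulus moments the pipeline's material mapping is
calibrated against.  :func:`clipped_normal_params` performs that moment
inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .grids import (
    BACKGROUND,
    LABEL_IDS,
    LEVELS,
    LabelMap,
    VoxelImage,
    cement_label,
    cortical_label,
    trabecular_label,
    vertebra_labels,
)

__all__ = [
    "PhantomSpec",
    "clipped_normal_params",
    "generate_phantom",
    "add_cement_region",
    "TARGET_BONE_MODULUS_MEAN",
    "TARGET_BONE_MODULUS_SD",
]

#: element-specific bone modulus moments the trabecular field reproduces (MPa)
TARGET_BONE_MODULUS_MEAN = 128.41
TARGET_BONE_MODULUS_SD = 66.20


def clipped_normal_params(
    target_mean: float, target_sd: float
) -> tuple[float, float]:
    """Invert the moments of ``max(N(mu, sigma), 0)``.

    Returns the ``(mu, sigma)`` of the generating Gaussian such that the
    zero-clipped variable has the requested mean and standard deviation.
    Clipping at zero inflates the mean and deflates the spread, so for a
    mean about two standard deviations above zero the correction is small
    but not negligible against a two-standard-error acceptance band.
    """

    def moments(p: np.ndarray) -> list[float]:
        mu, sigma = p
        a = mu / sigma
        Phi, phi = stats.norm.cdf(a), stats.norm.pdf(a)
        m1 = mu * Phi + sigma * phi
        m2 = (mu * mu + sigma * sigma) * Phi + mu * sigma * phi
        return [m1 - target_mean, math.sqrt(m2 - m1 * m1) - target_sd]

    sol, info, ok, msg = optimize.fsolve(
        moments, [target_mean, target_sd], full_output=True
    )
    if ok != 1:
        raise RuntimeError(f"clipped-normal moment inversion failed: {msg}")
    return float(sol[0]), float(sol[1])


# population moments of the default trabecular greyscale, computed once
_DEFAULT_GREY = clipped_normal_params(TARGET_BONE_MODULUS_MEAN, TARGET_BONE_MODULUS_SD)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, greyscale and seeding of the synthetic segment.

    All lengths are millimetres.  Axial heights must be whole multiples of
    ``voxel_size`` so the stack maps onto the grid without fractional
    voxels.  Defaults approximate an elderly female thoracolumbar segment:
    vertebral bodies ~32 x 23 mm across and ~25 mm tall, ~8 mm discs.
    """

    voxel_size: float = 1.4
    body_radius_lat: float = 16.0
    body_radius_ap: float = 11.5
    body_height: float = 25.2  # 18 voxels
    disc_height: float = 8.4  # 6 voxels
    cortical_thickness: float = 1.4  # one voxel shell
    nucleus_radius_fraction: float = 0.5
    housing_height: float = 5.6  # 4 voxels
    trabecular_grey_mean: float = _DEFAULT_GREY[0]
    trabecular_grey_sd: float = _DEFAULT_GREY[1]
    grey_cortical: float = 800.0
    grey_annulus: float = 30.0
    grey_nucleus: float = 10.0
    grey_housing: float = 1200.0
    grey_cement: float = 1600.0
    seed: int = 42
    levels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        for name in (
            "voxel_size",
            "body_radius_lat",
            "body_radius_ap",
            "body_height",
            "disc_height",
            "cortical_thickness",
            "housing_height",
            "trabecular_grey_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.nucleus_radius_fraction < 1.0:
            raise ValueError("nucleus_radius_fraction must lie strictly in (0, 1)")
        if self.cortical_voxels < 1:
            raise ValueError("cortical_thickness must be at least one voxel")
        for name in ("body_height", "disc_height", "housing_height", "cortical_thickness"):
            v = getattr(self, name) / self.voxel_size
            if abs(v - round(v)) > 1e-6:
                raise ValueError(
                    f"{name} = {getattr(self, name)} mm is not a whole number of "
                    f"{self.voxel_size} mm voxels"
                )
        if tuple(self.levels) != LEVELS:
            raise ValueError(f"levels must be {LEVELS}")

    # -- derived grid quantities ------------------------------------------
    def _vox(self, length: float) -> int:
        return int(round(length / self.voxel_size))

    @property
    def cortical_voxels(self) -> int:
        return self._vox(self.cortical_thickness)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        nx = 2 * (self._vox(self.body_radius_lat) + 1)
        ny = 2 * (self._vox(self.body_radius_ap) + 1)
        nz = (
            3 * self._vox(self.body_height)
            + 2 * self._vox(self.disc_height)
            + 2 * self._vox(self.housing_height)
        )
        return nx, ny, nz

    def axial_extents(self) -> dict[str, tuple[int, int]]:
        """Half-open axial voxel slab [k0, k1) of every stacked component,
        bottom (caudal) to top (cranial): housing, L2, disc, L1, disc, T12,
        housing."""
        hb = self._vox(self.housing_height)
        bb = self._vox(self.body_height)
        dd = self._vox(self.disc_height)
        k = 0
        out: dict[str, tuple[int, int]] = {}
        for name, width in (
            ("housing_bottom", hb),
            ("L2", bb),
            ("disc_lower", dd),
            ("L1", bb),
            ("disc_upper", dd),
            ("T12", bb),
            ("housing_top", hb),
        ):
            out[name] = (k, k + width)
            k += width
        return out


def _ellipse_mask(spec: PhantomSpec, radius_lat: float, radius_ap: float) -> np.ndarray:
    """2-D cross-section mask of voxels whose centres fall inside the ellipse
    centred on the grid axis."""
    nx, ny, _ = spec.grid_shape
    h = spec.voxel_size
    cx, cy = nx * h / 2.0, ny * h / 2.0
    x = (np.arange(nx) + 0.5) * h - cx
    y = (np.arange(ny) + 0.5) * h - cy
    X, Y = np.meshgrid(x, y, indexing="ij")
    return (X / radius_lat) ** 2 + (Y / radius_ap) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelImage, LabelMap]:
    """Build the synthetic segment's greyscale image and label map.

    The label map is purely geometric (independent of the seed); only the
    trabecular greyscale field is random.  Running twice with the same spec
    is bit-identical.
    """
    nx, ny, nz = spec.grid_shape
    t = spec.cortical_voxels
    h = spec.voxel_size

    inner_lat = spec.body_radius_lat - t * h
    inner_ap = spec.body_radius_ap - t * h
    if inner_lat <= 0 or inner_ap <= 0:
        raise ValueError(
            "grid too small: cortical shell consumes the whole cross-section"
        )
    body2d = _ellipse_mask(spec, spec.body_radius_lat, spec.body_radius_ap)
    inner2d = _ellipse_mask(spec, inner_lat, inner_ap)
    nucleus2d = _ellipse_mask(
        spec,
        spec.nucleus_radius_fraction * spec.body_radius_lat,
        spec.nucleus_radius_fraction * spec.body_radius_ap,
    )
    if not inner2d.any():
        raise ValueError(
            "grid too small: cortical shell consumes the whole cross-section"
        )
    if not body2d.any() or not nucleus2d.any():
        raise ValueError("grid too small to contain the vertebral cross-section")

    labels = np.zeros((nx, ny, nz), dtype=np.int64)
    extents = spec.axial_extents()

    for name, (k0, k1) in extents.items():
        sl = labels[:, :, k0:k1]
        if name.startswith("housing"):
            sl[body2d] = LABEL_IDS[name]
        elif name.startswith("disc"):
            which = "upper" if name == "disc_upper" else "lower"
            sl[body2d & ~nucleus2d] = LABEL_IDS[f"annulus_{which}"]
            sl[nucleus2d] = LABEL_IDS[f"nucleus_{which}"]
        else:  # a vertebral body: cortical shell (rim + endplates) around trabecular core
            sl[body2d] = cortical_label(name)
            core = sl[:, :, t : (k1 - k0) - t]
            core[inner2d] = trabecular_label(name)
    if not all((labels == trabecular_label(lv)).any() for lv in spec.levels):
        raise ValueError("grid too small: a vertebral body has no trabecular core")

    rng = np.random.default_rng(spec.seed)
    grey = np.zeros((nx, ny, nz), dtype=float)
    trab = np.isin(labels, [trabecular_label(lv) for lv in spec.levels])
    grey[trab] = np.clip(
        rng.normal(spec.trabecular_grey_mean, spec.trabecular_grey_sd, int(trab.sum())),
        0.0,
        None,
    )
    constants = {
        "cortical": spec.grey_cortical,
        "annulus": spec.grey_annulus,
        "nucleus": spec.grey_nucleus,
        "housing": spec.grey_housing,
        "cement": spec.grey_cement,
    }
    for lid, name in LabelMap(labels, h).names.items():
        stem = name.split("_")[0]
        if stem in constants and lid in labels:
            grey[labels == lid] = constants[stem]

    return VoxelImage(grey, h), LabelMap(labels, h)


def add_cement_region(
    labels: LabelMap, level: str, fill_fraction: float
) -> LabelMap:
    """Re-label a centrally seeded ball of trabecular voxels as cement.

    The region emulates an intravertebral cement bolus at a prescribed fill
    fraction of the vertebral-body volume (trabecular + cortical + any
    existing cement).  Voxels are converted in deterministic order of
    squared distance from the body centroid, ties broken by array index, so
    the region is reproducible and grows monotonically with the fraction.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError("fill_fraction must lie in [0, 1]")
    out = labels.copy()
    if fill_fraction == 0.0:
        return out

    body = out.mask(*vertebra_labels(level))
    trab = out.mask(trabecular_label(level))
    n_body = int(body.sum())
    n_existing = int(out.mask(cement_label(level)).sum())
    n_target = int(round(fill_fraction * n_body))
    n_new = n_target - n_existing
    max_frac = (n_existing + int(trab.sum())) / n_body
    if n_new > int(trab.sum()):
        raise ValueError(
            f"fill_fraction {fill_fraction:.3f} exceeds the available trabecular "
            f"volume of {level}; maximum achievable fraction is {max_frac:.3f}"
        )
    if n_new <= 0:
        return out

    idx = np.argwhere(trab)
    centroid = np.argwhere(body).mean(axis=0)
    d2 = ((idx - centroid) ** 2).sum(axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    chosen = idx[order[:n_new]]
    out.data[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = cement_label(level)
    return out
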