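"""Inverse calibration of intervertebral disc properties.

Disc tissue condition cannot be read from CT greyscale, so the pipeline
reverse-engineers it: starting from healthy literature properties, all disc
stiffness constants are scaled — preserving the annulus anisotropy ratios
exactly — until the model's simulated segmental stiffness matches the
experimentally measured pre-augmentation stiffness of the specimen.

A single search variable drives the annulus factor; the nucleus factor is
slaved through a power-law coupling ``nucleus_factor = annulus_factor**s``
with s = ln 4.9 / ln 2.625 ~ 1.647 by default — the exponent implied by
the healthy-to-degenerated transition of the reference property table,
where the nucleus stiffens 4.9x while the annulus axial modulus rises
21/8 = 2.625x.  The power law keeps the healthy state an exact fixed point
(factor 1 maps to factor 1) while reproducing that transition.  One
stiffness measurement cannot identify two independent factors, so there is
no independent two-variable search.  Poisson ratios are never scaled: the reference table shows them
changing non-proportionally between disc states, and scaling them risks
leaving the admissible range.

Segmental stiffness is strictly increasing in the disc factor (stiffening
any element can only stiffen the structure), so the target is bracketed on
a log-factor interval and located by bisection with an Illinois
(regula-falsi) acceleration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fe_core import Model, assemble, segment_stiffness, solve_system
from .materials import (
    Material,
    degenerated_annulus,
    degenerated_nucleus,
    healthy_annulus,
    healthy_nucleus,
)

__all__ = [
    "DiscProperties",
    "CalibrationResult",
    "scale_disc",
    "calibrate",
    "NUCLEUS_COUPLING_EXPONENT",
]

#: default power-law coupling exponent, ln(4.9/1) / ln(21/8)
NUCLEUS_COUPLING_EXPONENT = math.log(4.9) / math.log(2.625)


@dataclass(frozen=True)
class DiscProperties:
    """Annulus (orthotropic) and nucleus (isotropic) material pair."""

    annulus: Material
    nucleus: Material

    def __post_init__(self) -> None:
        if self.annulus.kind != "orthotropic":
            raise ValueError("annulus must be orthotropic")
        if self.nucleus.kind != "isotropic":
            raise ValueError("nucleus must be isotropic")

    @classmethod
    def healthy(cls) -> "DiscProperties":
        return cls(annulus=healthy_annulus(), nucleus=healthy_nucleus())

    @classmethod
    def degenerated(cls) -> "DiscProperties":
        return cls(annulus=degenerated_annulus(), nucleus=degenerated_nucleus())


def scale_disc(
    disc: DiscProperties, annulus_factor: float, nucleus_factor: float
) -> DiscProperties:
    """Scale disc stiffness constants, preserving anisotropy ratios.

    All three annulus Young's moduli and all three shear moduli are
    multiplied by ``annulus_factor`` (so E2/E1 and E3/E1 are preserved
    exactly); the nucleus modulus by ``nucleus_factor``.  Poisson ratios
    are left untouched.
    """
    if annulus_factor <= 0 or nucleus_factor <= 0:
        raise ValueError("scale factors must be positive")
    return DiscProperties(
        annulus=disc.annulus.scaled(annulus_factor),
        nucleus=disc.nucleus.scaled(nucleus_factor),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the one-dimensional disc-stiffness search."""

    annulus_factor: float
    nucleus_factor: float
    iterations: int
    achieved_k: float
    target_k: float
    converged: bool
    disc: DiscProperties

    @property
    def relative_error(self) -> float:
        return abs(self.achieved_k - self.target_k) / self.target_k


def calibrate(
    model_builder: Callable[[DiscProperties], Model],
    healthy: "DiscProperties | None" = None,
    target_k: float = 617.0,
    tolerance: float = 1e-3,
    coupling: float = NUCLEUS_COUPLING_EXPONENT,
    bracket: tuple[float, float] = (1.0 / 16.0, 16.0),
    max_iter: int = 60,
    applied_displacement: float = 0.5,
    solver: str = "auto",
) -> CalibrationResult:
    """Tune disc properties until the model stiffness matches ``target_k``.

    ``model_builder`` maps a :class:`DiscProperties` to a ready
    :class:`~vertefem.fe_core.Model` of the pre-treatment segment.  The
    search walks the annulus factor on a log scale inside ``bracket``
    (nucleus factor = annulus factor ** ``coupling``) until the relative
    stiffness mismatch falls below ``tolerance``.

    Because only the disc element matrices change between iterations, the
    invariant part of the global stiffness is assembled once and the two
    disc blocks are re-scaled algebraically — each iteration costs one
    linear solve, not one assembly.
    """
    if target_k <= 0:
        raise ValueError("target stiffness must be positive")
    healthy = healthy if healthy is not None else DiscProperties.healthy()

    base = model_builder(healthy)
    ann_mask = base.annulus_mask
    nuc_mask = base.element_mask("nucleus_upper", "nucleus_lower")
    other = ~(ann_mask | nuc_mask)
    K_other = assemble(base, other)
    K_ann = assemble(base, ann_mask)
    K_nuc = assemble(base, nuc_mask)

    warm: dict = {"x0": None}

    def stiffness_at(factor: float) -> float:
        K = K_other + factor * K_ann + (factor**coupling) * K_nuc
        res = solve_system(
            base, K, applied_displacement, solver=solver, x0=warm["x0"]
        )
        warm["x0"] = res.reduced
        return segment_stiffness(res).k

    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < lo < hi")
    evals = 0

    def f(factor: float) -> float:
        nonlocal evals
        evals += 1
        return stiffness_at(factor) - target_k

    f_lo, f_hi = f(lo), f(hi)
    if not f_lo <= 0 <= f_hi:
        raise ValueError(
            f"target stiffness {target_k:.1f} N/mm lies outside the achievable "
            f"bracket [{f_lo + target_k:.1f}, {f_hi + target_k:.1f}] N/mm for "
            f"factors [{lo:g}, {hi:g}]"
        )

    # Illinois regula falsi on log-factor; monotone k guarantees convergence
    a, fa = math.log(lo), f_lo
    b, fb = math.log(hi), f_hi
    best_x, best_f = (a, fa) if abs(fa) < abs(fb) else (b, fb)
    converged = abs(best_f) / target_k <= tolerance
    side = 0
    while not converged and evals < max_iter:
        x = (a * fb - b * fa) / (fb - fa)
        # guard against stagnation at an endpoint
        if not (min(a, b) < x < max(a, b)):
            x = 0.5 * (a + b)
        fx = f(math.exp(x))
        if abs(fx) < abs(best_f):
            best_x, best_f = x, fx
        if fx * fa < 0:
            b, fb = x, fx
            if side == -1:
                fa *= 0.5
            side = -1
        else:
            a, fa = x, fx
            if side == 1:
                fb *= 0.5
            side = 1
        converged = abs(best_f) / target_k <= tolerance

    factor = math.exp(best_x)
    disc = scale_disc(healthy, factor, factor**coupling)
    return CalibrationResult(
        annulus_factor=factor,
        nucleus_factor=factor**coupling,
        iterations=evals,
        achieved_k=best_f + target_k,
        target_k=target_k,
        converged=converged,
        disc=disc,
    )
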