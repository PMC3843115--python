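"""Parametric sweeps and stress-redistribution statistics.

The comparison convention mirrors a displacement-controlled platen test
re-expressed at a common load: every solve is linearly rescaled to the same
reaction force (1000 N by default) before stresses are differenced, so
treated and untreated states are compared at the same load level rather
than the same displacement.

For each vertebra the per-element von Mises change
``100 * (vm_post - vm_pre) / vm_pre`` is histogrammed with counts
normalised by the total element count of that vertebra; elements whose
pre-treatment stress is below a floor are routed to an explicit
"undefined" bucket so the histogram mass always sums to one.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, DiscProperties, calibrate
from .fe_core import (
    Model,
    SolveResult,
    assemble,
    build_model,
    element_stresses,
    segment_stiffness,
    solve_system,
    von_mises,
)
from .grids import LEVELS, LabelMap, cortical_label, trabecular_label, cement_label
from .imaging import ModulusField, greyscale_to_modulus
from .phantom import PhantomSpec, add_cement_region, generate_phantom
from .treatment import TreatmentConfig, apply_augmentation, scale_bone_quality, set_disc_state

__all__ = [
    "COMMON_REACTION_N",
    "StressChangeHistogram",
    "StudyRecord",
    "scale_to_common_load",
    "stress_change",
    "histogram",
    "default_bin_edges",
    "run_sweep",
    "cement_modulus_cells",
    "stiffness_grid_cells",
    "augmentation_pattern_cells",
]

log = logging.getLogger("vertefem.study")

#: load level at which treated and untreated stress fields are compared, N
COMMON_REACTION_N = 1000.0

#: pre-treatment von Mises floor below which a change is undefined, MPa
PRESTRESS_FLOOR = 1e-9


def scale_to_common_load(
    result: SolveResult, target_reaction: float = COMMON_REACTION_N
) -> SolveResult:
    """Rescale a solve so its reaction equals ``target_reaction`` exactly.

    Valid by linearity: displacements, stresses and reactions share one
    common factor, and the stiffness ratio is unchanged.
    """
    if result.reaction <= 0:
        raise ValueError("reaction must be positive to rescale")
    return result.scaled(target_reaction / result.reaction)


def stress_change(
    pre: SolveResult,
    post: SolveResult,
    model_pre: Model,
    model_post: Model,
    vertebra: str,
    prestress_floor: float = PRESTRESS_FLOOR,
) -> tuple[np.ndarray, int, int]:
    """Per-element percentage von Mises change in one vertebra's bone.

    Both solves must be expressed at the common reaction force.  Returns
    ``(changes, n_undefined, n_total)`` where ``changes`` covers elements
    with defined pre-stress and ``n_total`` counts every bone element of
    the vertebra (the pre-treatment trabecular + cortical + cement-region
    set, identical in both models by construction).
    """
    if model_pre.conn.shape != model_post.conn.shape or not np.array_equal(
        model_pre.conn, model_post.conn
    ):
        raise ValueError("pre and post models are not on the same mesh")
    for r in (pre, post):
        if abs(r.reaction - COMMON_REACTION_N) > 1e-6 * COMMON_REACTION_N:
            raise ValueError(
                "stress comparison requires both solves at the common "
                f"reaction of {COMMON_REACTION_N:g} N; got {r.reaction:.3f} N"
            )
    mask = model_pre.element_mask(
        f"trabecular_{vertebra}", f"cortical_{vertebra}", f"cement_{vertebra}"
    )
    vm_pre = von_mises(element_stresses(model_pre, pre))[mask]
    vm_post = von_mises(element_stresses(model_post, post))[mask]
    defined = vm_pre > prestress_floor
    changes = 100.0 * (vm_post[defined] - vm_pre[defined]) / vm_pre[defined]
    return changes, int((~defined).sum()), int(mask.sum())


def default_bin_edges(lo: float = -100.0, hi: float = 100.0, width: float = 10.0) -> np.ndarray:
    """10-percentage-point bins over [-100, 100]; open tails are added by
    :func:`histogram`."""
    return np.arange(lo, hi + 0.5 * width, width)


@dataclass
class StressChangeHistogram:
    """Normalised distribution of per-element stress change in one vertebra."""

    vertebra: str
    bin_edges: np.ndarray  # interior edges; first/last bins are open tails
    fractions: np.ndarray  # len(bin_edges) + 1 entries
    undefined_fraction: float
    n_elements: int

    def __post_init__(self) -> None:
        total = self.fractions.sum() + self.undefined_fraction
        if abs(total - 1.0) > 1e-12:
            raise AssertionError(f"histogram mass {total} != 1")

    @property
    def mass_below_zero(self) -> float:
        edges = np.asarray(self.bin_edges)
        below = edges <= 0
        # bins fully below zero: bin i spans (edges[i-1], edges[i]); bin 0 is (-inf, edges[0])
        frac = self.fractions[0]
        for i in range(1, len(edges)):
            if edges[i] <= 0:
                frac += self.fractions[i]
        return float(frac)

    @property
    def mass_above_zero(self) -> float:
        frac = self.fractions[-1]
        edges = np.asarray(self.bin_edges)
        for i in range(1, len(edges)):
            if edges[i - 1] >= 0:
                frac += self.fractions[i]
        return float(frac)


def histogram(
    changes: np.ndarray,
    n_undefined: int,
    n_total: int,
    vertebra: str = "",
    bin_edges: "np.ndarray | None" = None,
) -> StressChangeHistogram:
    """Bin percentage changes with half-open [lo, hi) bins and open tails.

    Fractions are normalised by ``n_total`` (all elements of the vertebra,
    the undefined bucket included) so mass is conserved exactly.
    """
    edges = np.asarray(bin_edges if bin_edges is not None else default_bin_edges(), float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if n_total != len(changes) + n_undefined:
        raise ValueError("n_total must equal defined + undefined element counts")
    idx = np.searchsorted(edges, changes, side="right")  # 0 = below lo tail
    counts = np.bincount(idx, minlength=len(edges) + 1).astype(float)
    return StressChangeHistogram(
        vertebra=vertebra,
        bin_edges=edges,
        fractions=counts / max(n_total, 1),
        undefined_fraction=n_undefined / max(n_total, 1),
        n_elements=n_total,
    )


@dataclass
class StudyRecord:
    """One parametric cell: its configuration, stiffness and histograms."""

    config: TreatmentConfig
    k: float
    histograms: dict[str, StressChangeHistogram]
    calibration: "CalibrationResult | None" = None
    seed: int = 0


# -- canonical parametric grids -------------------------------------------

def cement_modulus_cells() -> list[TreatmentConfig]:
    """Augmented-region modulus from pure cement down to 12.5% composite."""
    return [
        TreatmentConfig(cement_modulus_fraction=f, label=f"cement_frac_{f:g}")
        for f in (1.0, 0.5, 0.25, 0.125)
    ]


def stiffness_grid_cells() -> list[TreatmentConfig]:
    """Disc state x bone quality x cement volume stiffness grid."""
    cells = []
    for disc in ("degenerated", "healthy"):
        for bone in (0.5, 1.0, 2.0):
            for vol in (0.5, 1.0, 2.0):
                cells.append(
                    TreatmentConfig(
                        disc_state=disc,
                        bone_factor=bone,
                        volume_factor=vol,
                        label=f"grid_{disc}_b{bone:g}_v{vol:g}",
                    )
                )
    return cells


def augmentation_pattern_cells() -> list[TreatmentConfig]:
    """Augmentation at T12, at both T12 and L1, and the untreated reference."""
    return [
        TreatmentConfig(augmented_levels=(), label="untreated"),
        TreatmentConfig(augmented_levels=("T12",), label="augment_T12"),
        TreatmentConfig(augmented_levels=("T12", "L1"), label="augment_T12_L1"),
    ]


@dataclass
class SweepResult:
    records: list[StudyRecord]
    calibration: CalibrationResult
    pre_k: float
    failures: list[tuple[str, str]] = field(default_factory=list)

    def stiffness_table(self) -> pd.DataFrame:
        rows = [
            {
                "cell": r.config.describe(),
                "disc_state": r.config.disc_state,
                "bone_factor": r.config.bone_factor,
                "volume_factor": r.config.volume_factor,
                "cement_E": r.config.effective_cement_E,
                "levels": "+".join(r.config.augmented_levels) or "none",
                "k_N_per_mm": r.k,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def histogram_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for v, h in r.histograms.items():
                edges = [-np.inf, *h.bin_edges, np.inf]
                for b, frac in enumerate(h.fractions):
                    rows.append(
                        {
                            "cell": r.config.describe(),
                            "vertebra": v,
                            "bin_lo": edges[b],
                            "bin_hi": edges[b + 1],
                            "fraction": frac,
                        }
                    )
                rows.append(
                    {
                        "cell": r.config.describe(),
                        "vertebra": v,
                        "bin_lo": np.nan,
                        "bin_hi": np.nan,
                        "fraction": h.undefined_fraction,
                    }
                )
        return pd.DataFrame(rows)


def run_sweep(
    cells: list[TreatmentConfig],
    spec: "PhantomSpec | None" = None,
    target_k: float = 617.0,
    common_reaction: float = COMMON_REACTION_N,
    stress_vertebrae: tuple[str, ...] = LEVELS,
    out_dir: "str | Path | None" = None,
    solver: str = "auto",
    applied_displacement: float = 0.5,
    bin_edges: "np.ndarray | None" = None,
) -> SweepResult:
    """Run the full pipeline for a list of treatment cells.

    One phantom is generated, its disc properties calibrated once against
    ``target_k`` on the pre-treatment model, and every cell is then built,
    treated, solved and compared (at the common reaction) against the
    pre-treatment reference sharing its disc state and bone quality.
    Failures in individual cells are recorded and skipped.
    """
    spec = spec if spec is not None else PhantomSpec()
    t_start = time.time()
    file_handler = None
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        file_handler = logging.FileHandler(Path(out_dir) / "study.log")
        file_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(file_handler)
        log.setLevel(logging.INFO)
    image, labels_pre = generate_phantom(spec)
    modulus = greyscale_to_modulus(image, labels_pre)

    def builder(labels: LabelMap):
        def build(disc: DiscProperties) -> Model:
            return build_model(labels, modulus, annulus=disc.annulus, nucleus=disc.nucleus)
        return build

    cal = calibrate(
        builder(labels_pre),
        target_k=target_k,
        applied_displacement=applied_displacement,
        solver=solver,
    )
    log.info(
        "calibration: factor %.4f achieved %.2f N/mm in %d evaluations",
        cal.annulus_factor, cal.achieved_k, cal.iterations,
    )
    disc_sets = {
        "degenerated": (cal.disc.annulus, cal.disc.nucleus),
        "healthy": (DiscProperties.healthy().annulus, DiscProperties.healthy().nucleus),
    }

    label_cache: dict = {}

    def labels_with_cement(levels: tuple[str, ...], fill: float) -> LabelMap:
        key = (tuple(sorted(levels)), round(fill, 9))
        if key not in label_cache:
            lm = labels_pre
            for lv in levels:
                lm = add_cement_region(lm, lv, fill)
            label_cache[key] = lm
        return label_cache[key]

    solve_cache: dict = {}
    warm: dict = {"x0": None}

    def solve_cell(
        levels: tuple[str, ...],
        fill: float,
        disc_state: str,
        bone_factor: float,
        cement_E: "float | None",
    ) -> tuple[Model, SolveResult, float]:
        key = (tuple(sorted(levels)), round(fill, 9), disc_state, bone_factor, cement_E)
        if key not in solve_cache:
            lm = labels_with_cement(levels, fill)
            ann, nuc = disc_sets[disc_state]
            model = build_model(lm, modulus, annulus=ann, nucleus=nuc)
            if bone_factor != 1.0:
                model = scale_bone_quality(model, bone_factor)
            if cement_E is not None and levels:
                model = apply_augmentation(model, levels, cement_E)
            res = solve_system(
                model, assemble(model), applied_displacement,
                solver=solver, x0=warm["x0"],
            )
            warm["x0"] = res.reduced
            solve_cache[key] = (model, res, segment_stiffness(res).k)
        return solve_cache[key]

    records: list[StudyRecord] = []
    failures: list[tuple[str, str]] = []
    pre_model, pre_res, pre_k = solve_cell((), 0.2, "degenerated", 1.0, None)

    for cfg in cells:
        name = cfg.describe()
        t0 = time.time()
        try:
            fill = cfg.fill_fraction * cfg.volume_factor
            model, res, k = solve_cell(
                cfg.augmented_levels,
                fill,
                cfg.disc_state,
                cfg.bone_factor,
                cfg.effective_cement_E if cfg.augmented_levels else None,
            )
            hists: dict[str, StressChangeHistogram] = {}
            if cfg.augmented_levels and stress_vertebrae:
                ref_model, ref_res, _ = solve_cell(
                    (), 0.2, cfg.disc_state, cfg.bone_factor, None
                )
                ref_c = scale_to_common_load(ref_res, common_reaction)
                post_c = scale_to_common_load(res, common_reaction)
                for v in stress_vertebrae:
                    ch, n_undef, n_tot = stress_change(ref_c, post_c, ref_model, model, v)
                    hists[v] = histogram(ch, n_undef, n_tot, v, bin_edges)
            records.append(
                StudyRecord(config=cfg, k=k, histograms=hists, calibration=cal, seed=spec.seed)
            )
            log.info("cell %-40s k=%8.2f N/mm  (%.1fs)", name, k, time.time() - t0)
        except Exception as exc:  # noqa: BLE001 - cell isolation is the point
            failures.append((name, str(exc)))
            log.error("cell %s failed: %s", name, exc)

    out = SweepResult(records=records, calibration=cal, pre_k=pre_k, failures=failures)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out.stiffness_table().to_csv(out_dir / "stiffness.csv", index=False)
        out.histogram_table().to_csv(out_dir / "histograms.csv", index=False)
    log.info("sweep finished: %d cells in %.1fs", len(records), time.time() - t_start)
    if file_handler is not None:
        log.removeHandler(file_handler)
        file_handler.close()
    return out
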