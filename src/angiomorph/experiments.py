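"""Phantom-anchored validation experiments.

The patient images behind the published cohort numbers are not deposited,
so validation runs parameter-recovery experiments: a phantom's ground
truth is *set* to a published cohort mean, the full pipeline measures the
phantom, and the measurement is compared against that mean. The functions
here are shared by the acceptance script, the test suite and the analysis
drivers.

Experiment configuration (chosen once, by QC inspection of development
phantoms, and documented in the methods note):

* Filter scales 0.3 and 0.6 mm — sigma bracketing the ~0.4 mm vessel radii
  present in the phantoms (the package-wide default ladder additionally
  covers 0.15 and 1.2 mm for real data of unknown caliber).
* Vesselness threshold 1000 arb. units (score 0.24 of the 4096 scale) —
  the per-VOI operator threshold of the original protocol, set where the
  phantom's background vesselness histogram has emptied but the vessel
  cross-sections are still full; phantoms are high-SNR so a moderate
  threshold suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .cohort import compare_cohorts, simulate_cohort
from .morphometry import METRICS, mean_diameter, quantify_voi
from .phantom import (
    PhantomSpec,
    apply_tof_intensity_model,
    control_preset,
    generate_phantom,
    generate_vessel_tree,
    rasterize_tree,
    tumor_preset,
)
from .volume import VOIMask

#: published cohort means the recovery experiments are anchored to
PAPER_TUMOR = {
    "n_branches_per_cm3": 3.5,
    "mean_branch_length_mm": 3.8,
    "total_surface_mm2_per_cm3": 45.3,
    "total_length_mm_per_cm3": 11.363,
    "total_volume_mm3_per_cm3": 5.633,
    "mean_diameter_mm": 0.803,
}
PAPER_CONTROL = {
    "n_branches_per_cm3": 1.0,
    "mean_branch_length_mm": 7.2,
    "total_surface_mm2_per_cm3": 29.0,
    "total_length_mm_per_cm3": 7.175,
    "total_volume_mm3_per_cm3": 4.1073,
    "mean_diameter_mm": 0.8541,
}

PHANTOM_SCALES_MM = (0.3, 0.6)
PHANTOM_THRESHOLD = 1000.0

_PRESETS = {"tumor": tumor_preset, "control": control_preset}


def phantom_pipeline_config() -> PipelineConfig:
    """Pipeline configuration used for all phantom experiments."""
    return PipelineConfig(scales_mm=PHANTOM_SCALES_MM, threshold=PHANTOM_THRESHOLD)


@dataclass
class RecoveryResult:
    """One recovery experiment: pipeline estimate vs ground truth vs paper."""

    metric: str
    preset: str
    measured: float
    truth: float
    paper: float
    n_voxels: int
    seed: int

    @property
    def rel_error_vs_truth(self) -> float:
        return (self.measured - self.truth) / self.truth

    @property
    def rel_error_vs_paper(self) -> float:
        return (self.measured - self.paper) / self.paper


def _measure(spec: PhantomSpec):
    image, voi, tree, truth = generate_phantom(spec)
    morpho = quantify_voi(image, voi, phantom_pipeline_config())
    return morpho, truth, voi


def _truth_density(truth, metric: str) -> float:
    """Ground-truth value of a metric (analytic tree; voxelized for
    volume/surface, where digitization is part of the quantity)."""
    voi = truth.voi_volume_cm3
    if metric == "n_branches_per_cm3":
        return truth.analytic["n_branches"] / voi
    if metric == "mean_branch_length_mm":
        return truth.analytic["mean_branch_length_mm"]
    if metric == "total_length_mm_per_cm3":
        return truth.analytic["total_length_mm"] / voi
    if metric == "total_volume_mm3_per_cm3":
        return truth.voxelized["volume_mm3"] / voi
    if metric == "total_surface_mm2_per_cm3":
        return truth.voxelized["surface_mm2"] / voi
    if metric == "mean_diameter_mm":
        return truth.analytic["mean_diameter_mm"]
    raise KeyError(metric)


def branch_density_recovery(preset: str, seed: int) -> RecoveryResult:
    """Recover branches/cm^3 on a ~10 cm^3 phantom anchored to the cohort
    mean branch density (tumor 3.5, control 1.0)."""
    spec = _PRESETS[preset](seed=seed)
    morpho, truth, voi = _measure(spec)
    return RecoveryResult(
        "n_branches_per_cm3", preset, morpho.n_branches_per_cm3,
        _truth_density(truth, "n_branches_per_cm3"),
        (PAPER_TUMOR if preset == "tumor" else PAPER_CONTROL)["n_branches_per_cm3"],
        int(np.prod(spec.grid_shape)), seed,
    )


def branch_length_recovery(preset: str, seed: int) -> RecoveryResult:
    """Recover mean branch length (mm) anchored to the cohort mean
    (tumor 3.8, control 7.2)."""
    spec = _PRESETS[preset](seed=seed)
    morpho, truth, voi = _measure(spec)
    return RecoveryResult(
        "mean_branch_length_mm", preset, morpho.mean_branch_length_mm,
        _truth_density(truth, "mean_branch_length_mm"),
        (PAPER_TUMOR if preset == "tumor" else PAPER_CONTROL)["mean_branch_length_mm"],
        int(np.prod(spec.grid_shape)), seed,
    )


def length_density_recovery(seed: int) -> RecoveryResult:
    """Recover total centerline length per cm^3 on a tumor phantom whose
    analytic length density is set to the printed tumor mean (11.363)."""
    target = PAPER_TUMOR["total_length_mm_per_cm3"]
    density = target / 3.8  # branch density giving the target length density
    spec = tumor_preset(seed=seed, branches_per_cm3_target=density)
    morpho, truth, voi = _measure(spec)
    return RecoveryResult(
        "total_length_mm_per_cm3", "tumor", morpho.total_length_mm_per_cm3,
        _truth_density(truth, "total_length_mm_per_cm3"), target,
        int(np.prod(spec.grid_shape)), seed,
    )


def calibrate_density(
    preset: str,
    metric: str,
    target: float,
    seed: int,
    n_iter: int = 4,
) -> PhantomSpec:
    """Tune the preset's tube count until the *ground-truth* voxelized
    density of ``metric`` (surface or volume per cm^3) hits ``target``.

    Tube count rather than diameter is the tuned knob so that the phantom
    keeps the cohort's printed mean vessel diameter. The oracle is the
    face-count / voxel-count truth on the rasterized mask, never the
    pipeline output: the pipeline is the thing under test. The achieved
    truth is quantized by the integer segment count (a few percent).
    """
    make = _PRESETS[preset]

    def truth_at(density: float):
        spec = make(seed=seed, branches_per_cm3_target=density)
        tree = generate_vessel_tree(spec)
        _, truth = rasterize_tree(tree, spec)
        return _truth_density(truth, metric), spec

    density = make(seed=seed).branches_per_cm3_target
    best = None
    for _ in range(n_iter):
        val, spec = truth_at(density)
        if best is None or abs(val - target) < abs(best[0] - target):
            best = (val, spec, density)
        if abs(val - target) / target < 0.01:
            break
        density *= target / val  # totals scale ~linearly with tube count
    return best[1]


def surface_density_recovery(seed: int) -> RecoveryResult:
    """Recover total vessel surface per cm^3 on a tumor phantom whose
    face-count ground-truth surface density is tuned to the printed 45.3."""
    target = PAPER_TUMOR["total_surface_mm2_per_cm3"]
    spec = calibrate_density("tumor", "total_surface_mm2_per_cm3", target, seed)
    morpho, truth, voi = _measure(spec)
    return RecoveryResult(
        "total_surface_mm2_per_cm3", "tumor", morpho.total_surface_mm2_per_cm3,
        _truth_density(truth, "total_surface_mm2_per_cm3"), target,
        int(np.prod(spec.grid_shape)), seed,
    )


def volume_density_recovery(seed: int) -> RecoveryResult:
    """Recover total vessel volume per cm^3 on a tumor phantom whose
    voxelized ground-truth volume density is tuned to the printed 5.633."""
    target = PAPER_TUMOR["total_volume_mm3_per_cm3"]
    spec = calibrate_density("tumor", "total_volume_mm3_per_cm3", target, seed)
    morpho, truth, voi = _measure(spec)
    return RecoveryResult(
        "total_volume_mm3_per_cm3", "tumor", morpho.total_volume_mm3_per_cm3,
        _truth_density(truth, "total_volume_mm3_per_cm3"), target,
        int(np.prod(spec.grid_shape)), seed,
    )


def control_mean_diameter_consistency() -> float:
    """Uniform-cylinder mean diameter implied by the printed control totals
    (V = 4.1073 mm^3/cm^3, L = 7.175 mm/cm^3); printed mean is 0.8541 mm."""
    return mean_diameter(
        PAPER_CONTROL["total_volume_mm3_per_cm3"],
        PAPER_CONTROL["total_length_mm_per_cm3"],
    )


def cohort_power(
    n_replicates: int = 200,
    n_subjects: int = 12,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of simulated cohorts in which each metric is significant.

    Replicate r uses cohort seed ``seed + r``.
    """
    hits = {m: 0 for m in METRICS}
    for rep in range(n_replicates):
        table = simulate_cohort(n_subjects=n_subjects, seed=seed + rep)
        results, _ = compare_cohorts(table, alpha=alpha)
        for r in results:
            if r.significant:
                hits[r.metric] += 1
    return {m: hits[m] / n_replicates for m in METRICS}


#: variability experiment geometry: three 12.4 cm^3 sub-VOIs of one
#: homogeneous control phantom (the published control VOIs averaged 13 cm^3)
_VARIABILITY_GRID = (210, 70, 66)


def variability_experiment(seed: int) -> pd.DataFrame:
    """Three non-overlapping sub-VOIs of one homogeneous control phantom.

    Mirrors the study's robustness check (three white-matter VOIs in one
    patient). Returns the per-sub-VOI metric table; the coefficient of
    variation per metric is the quantity of interest.
    """
    spec = control_preset(grid_shape=_VARIABILITY_GRID, seed=seed)
    image, voi, tree, truth = generate_phantom(spec)
    config = phantom_pipeline_config()
    rows = []
    n_sub = 3
    width = _VARIABILITY_GRID[0] // n_sub
    for i in range(n_sub):
        sub = np.zeros(spec.grid_shape, dtype=bool)
        sub[i * width:(i + 1) * width] = True
        m = quantify_voi(image, VOIMask(sub, spec.spacing_mm), config)
        rows.append({"sub_voi": i + 1, **m.as_dict()})
    return pd.DataFrame(rows)


def variability_cv(table: pd.DataFrame) -> dict:
    """Coefficient of variation (SD/mean) per metric across sub-VOIs."""
    return {
        m: float(table[m].std(ddof=1) / table[m].mean()) for m in METRICS
    }
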