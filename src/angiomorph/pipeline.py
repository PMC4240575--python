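"""End-to-end orchestration: phantom or NIfTI input -> per-VOI metrics CSV.

Stage order follows the published postprocessing chain: vessel
enhancement, thresholding with 3D object counting, skeletonization and
skeleton analysis, then per-cm^3 standardization. Runs are deterministic
for a fixed config and inputs; every output row carries the config hash.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .morphometry import quantify_voi
from .volume import ImageVolume, VOIMask, load_mask, load_volume, save_nifti

log = logging.getLogger(__name__)


def run_full_pipeline(
    image,
    voi_masks: dict,
    config: PipelineConfig | None = None,
    out_dir=None,
    write_intermediates: bool = False,
) -> pd.DataFrame:
    """Quantify every VOI of one image; returns one metrics row per VOI.

    ``image`` is an ``ImageVolume`` or a NIfTI path; ``voi_masks`` maps VOI
    names to ``VOIMask`` objects or NIfTI paths. With ``out_dir`` set, the
    metrics table is written as ``morphometry.csv`` (and, when requested,
    stage intermediates as NIfTI per VOI).
    """
    config = config or PipelineConfig()
    if not isinstance(image, ImageVolume):
        path = Path(image)
        if not path.exists():
            raise FileNotFoundError(f"image volume not found: {path}")
        image = load_volume(path)

    rows = []
    for name, voi in voi_masks.items():
        if not isinstance(voi, VOIMask):
            vpath = Path(voi)
            if not vpath.exists():
                raise FileNotFoundError(f"VOI mask not found for {name!r}: {vpath}")
            voi = load_mask(vpath)
        if voi.shape != image.shape:
            raise ValueError(
                f"VOI {name!r} grid {voi.shape} does not match image grid {image.shape}"
            )
        t0 = time.perf_counter()
        inter: dict = {}
        morpho = quantify_voi(image, voi, config, intermediates=inter)
        log.info(
            "VOI %s: %d voxels, %d objects, %d branches (%.1f s)",
            name, voi.voxel_count, inter["objects"].n_objects,
            inter["graph"].n_branches, time.perf_counter() - t0,
        )
        row = {"voi": name, **morpho.as_dict(), "config_hash": config.config_hash()}
        rows.append(row)
        if out_dir is not None and write_intermediates:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            spacing = image.spacing_mm
            save_nifti(ImageVolume(inter["enhanced"], spacing), out / f"{name}_vesselness.nii.gz")
            save_nifti(VOIMask(inter["mask"], spacing), out / f"{name}_mask.nii.gz")
            save_nifti(ImageVolume(inter["objects"].labels.astype(np.float64), spacing),
                       out / f"{name}_labels.nii.gz")
            save_nifti(VOIMask(inter["skeleton"], spacing), out / f"{name}_skeleton.nii.gz")

    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "morphometry.csv", index=False)
        config.to_json(out / "config.json")
    return table


def max_intensity_projection(vol: ImageVolume | np.ndarray, axis: int = 2) -> np.ndarray:
    """Per-pixel maximum along one axis — the standard angiographic QC view."""
    data = vol.data if isinstance(vol, ImageVolume) else np.asarray(vol)
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return data.max(axis=axis)


def save_mip_png(vol, path, axis: int = 2) -> None:
    """Write a maximum intensity projection as a grayscale PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mip = max_intensity_projection(vol, axis=axis)
    plt.imsave(str(path), mip.T, cmap="gray", origin="lower")
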