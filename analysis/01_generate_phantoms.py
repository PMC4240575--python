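"""Generate one tumor-like and one control-like ToF phantom.

Writes the NIfTI volumes, ground-truth JSON and QC maximum-intensity
projections under results/phantoms/. The tumor phantom is dense, short-
branched, tortuous and dimmer; the control phantom sparse, long and
straight — the two vascular regimes the cohort comparison rests on.
"""

from pathlib import Path

import angiomorph as am
from angiomorph.pipeline import save_mip_png
from angiomorph.volume import VOIMask

OUT = Path(__file__).resolve().parent.parent / "results" / "phantoms"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, preset in (("tumor", am.tumor_preset), ("control", am.control_preset)):
        spec = preset(seed=1)
        image, voi, tree, truth = am.generate_phantom(spec)
        d = OUT / name
        d.mkdir(exist_ok=True)
        am.save_nifti(image, d / "image.nii.gz")
        am.save_nifti(voi, d / "voi.nii.gz")
        am.save_nifti(VOIMask(truth.voxelized["mask"], spec.spacing_mm), d / "true_mask.nii.gz")
        truth.to_json(d / "truth.json")
        spec.to_json(d / "spec.json")
        save_mip_png(image, d / "mip.png", axis=2)
        a = truth.analytic
        print(
            f"{name}: {tree.n_segments} segments in {spec.voi_volume_cm3:.1f} cm^3 "
            f"({a['n_branches'] / truth.voi_volume_cm3:.2f}/cm^3), "
            f"mean branch length {a['mean_branch_length_mm']:.2f} mm, "
            f"mean diameter {a['mean_diameter_mm']:.3f} mm -> {d}"
        )


if __name__ == "__main__":
    main()
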