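"""Pipeline configuration: every stage parameter in one serializable object.

Defaults follow the published protocol where a value is printed (threshold
2200 arb. units, minimum object size 4 voxels, voxel size
0.31 x 0.31 x 0.40 mm, alpha level 0.05) and this package's documented
choices otherwise. Each run's outputs carry ``config_hash()`` so results
are traceable to the exact parameterization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

from .vesselness import DEFAULT_SCALES_MM, VesselnessParams


@dataclass
class PipelineConfig:
    # vessel enhancement
    scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None  # None = half max Hessian Frobenius norm per scale
    mode: str = "frangi3d"
    gamma_normalization: float = 2.0
    #: the vesselness score in [0,1] is reported on this arbitrary-unit scale
    #: so thresholds are comparable to 12-bit ToF intensity conventions
    vesselness_scale: float = 4096.0
    # segmentation
    threshold: float = 2200.0
    min_voxels: int = 4
    connectivity: int = 26
    # skeleton
    prune_below_length_mm: float | None = None
    # statistics
    alpha_level: float = 0.05
    seed: int = 0

    def vesselness_params(self) -> VesselnessParams:
        return VesselnessParams(
            scales_mm=tuple(self.scales_mm),
            alpha=self.alpha,
            beta=self.beta,
            c=self.c,
            mode=self.mode,
            gamma_normalization=self.gamma_normalization,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales_mm"] = list(self.scales_mm)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as f:
            d = json.load(f)
        d["scales_mm"] = tuple(d["scales_mm"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
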