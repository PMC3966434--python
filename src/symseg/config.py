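"""Pipeline configuration: one flat record of every tunable.

Defaults are the package's study conditions; every value can be overridden
from a YAML file (``PipelineConfig.from_file``) or, on the CLI, by flags
(flags win over the file).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .chanvese import ChanVeseParams
from .errors import ParameterError


@dataclass
class PipelineConfig:
    """All knobs of the HASA / EHASA / baseline pipelines.

    preprocess_enabled   run grayscale morphology before the symmetry stage.
    preprocess_radius    disk radius of the structuring element (px).
    preprocess_mode      "open" (erosion then dilation), "close", "open-close".
    shift_search         estimate an integer midline offset (±10% of width)
                         before reflecting; off by default — the reflection
                         axis is the geometric image midline.
    seed_frac            seed threshold as a fraction of the rectified
                         difference maximum.
    seed_min_area        smallest connected component (px) kept as a seed.
    noise_floor          rectified-difference maximum below which the slice
                         is declared asymmetry-free (no-tumor signal).
    ehasa_fraction       the binarization threshold T as a fraction of the
                         original image's maximum intensity (T = 0.25·max(O)
                         by default).
    ehasa_use_mean       alternative threshold T = mean of the rectified
                         difference (fidelity experiment; off by default).
    drop_border_regions  discard final components touching the image border.
    chanvese             active-contour parameters (ChanVeseParams).
    verbose              keep/emit every intermediate stage image.
    """

    preprocess_enabled: bool = True
    preprocess_radius: int = 2
    preprocess_mode: str = "open"
    shift_search: bool = False
    seed_frac: float = 0.5
    seed_min_area: int = 10
    noise_floor: float = 0.05
    ehasa_fraction: float = 0.25
    ehasa_use_mean: bool = False
    drop_border_regions: bool = False
    chanvese: ChanVeseParams = field(default_factory=ChanVeseParams)
    verbose: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.seed_frac < 1:
            raise ParameterError(f"seed_frac must be in (0, 1), got {self.seed_frac}")
        if int(self.seed_min_area) < 1:
            raise ParameterError(f"seed_min_area must be >= 1, got {self.seed_min_area}")
        if self.noise_floor < 0:
            raise ParameterError(f"noise_floor must be >= 0, got {self.noise_floor}")
        if not 0 < self.ehasa_fraction < 1:
            raise ParameterError(
                f"ehasa_fraction must be in (0, 1), got {self.ehasa_fraction}"
            )

    def to_dict(self) -> dict:
        d = {
            "preprocess_enabled": self.preprocess_enabled,
            "preprocess_radius": self.preprocess_radius,
            "preprocess_mode": self.preprocess_mode,
            "shift_search": self.shift_search,
            "seed_frac": self.seed_frac,
            "seed_min_area": self.seed_min_area,
            "noise_floor": self.noise_floor,
            "ehasa_fraction": self.ehasa_fraction,
            "ehasa_use_mean": self.ehasa_use_mean,
            "drop_border_regions": self.drop_border_regions,
            "verbose": self.verbose,
        }
        d["chanvese"] = self.chanvese.to_dict()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        cv = data.pop("chanvese", {})
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(chanvese=ChanVeseParams(**cv), **data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
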