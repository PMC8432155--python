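"""Study configuration: every analysis constant is config-visible here.

The defaults hold the frozen screening constants (nuclear threshold 144,
ACN threshold 2000, aggregate-area threshold 969, maxima tolerances
150/1000) and the mitochondrial volume bin bounds (100, 1000).  The
nuclear threshold can instead be recalibrated per batch by setting
``threshold_mode: batch-otsu``; the frozen value is the default for
reproducibility across reanalysis runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from ..errors import InputError

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    # input / output
    layout_path: Optional[str] = None
    output_dir: str = "results"
    seed: int = 0
    control_line: str = "30CAG"

    # nuclear segmentation
    threshold_mode: str = "frozen"  # "frozen" | "batch-otsu"
    nuclear_threshold: float = 144.0
    min_nucleus_area: int = 50
    min_seed_separation: int = 7

    # inclusion metrics
    acn_threshold: float = 2000.0
    area_threshold: float = 969.0
    spot_tolerance: float = 150.0
    total_tolerance: float = 1000.0
    background_cutoff: float = 2000.0
    ring_width: int = 3
    na_area_all_nuclei_denominator: bool = True

    # mitochondrial volume bins
    volume_bounds: tuple = (100.0, 1000.0)

    # demo plate (simulate verb)
    lines: tuple = ("30CAG", "71CAG", "122CAG")
    days: tuple = (0, 4, 7, 14)
    wells_per_line: int = 4
    field_shape: tuple = (256, 256)
    n_nuclei: int = 30

    def __post_init__(self) -> None:
        for name in ("nuclear_threshold", "acn_threshold", "area_threshold",
                     "spot_tolerance", "total_tolerance", "background_cutoff"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if self.threshold_mode not in ("frozen", "batch-otsu"):
            raise InputError(
                f"threshold_mode must be 'frozen' or 'batch-otsu'; "
                f"got {self.threshold_mode!r}"
            )
        self.volume_bounds = tuple(self.volume_bounds)
        self.lines = tuple(self.lines)
        self.days = tuple(int(d) for d in self.days)
        if not self.lines or not self.days:
            raise InputError("config must name at least one line and one day")
        self.field_shape = tuple(int(x) for x in self.field_shape)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"config file {path} must hold a mapping")
        data.update(overrides)
        valid = set(cls.__dataclass_fields__)
        unknown = set(data) - valid
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
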