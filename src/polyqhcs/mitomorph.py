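"""Mitochondrial volume classification and control-relative intensities.

Organelle volumes (um^3) are binned as small / medium / large with the
medium bin closed on both ends ([lo, hi]) and small/large strict; the
reported percentages are volume-weighted (each bin's share of total
mitochondrial volume), not object counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "MitoVolumeSet",
    "DEFAULT_BOUNDS",
    "volume_fractions",
    "pct_of_control",
    "read_volumes_csv",
    "fractions_frame",
]

DEFAULT_BOUNDS = (100.0, 1000.0)


@dataclass
class MitoVolumeSet:
    volumes: np.ndarray  # um^3 per detected organelle
    line_label: str = ""
    replicate_id: str = ""
    tmrm_mean_intensity_per_volume: Optional[float] = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.size and np.any(self.volumes <= 0):
            raise InputError("all volumes must be > 0")


def volume_fractions(
    vset: MitoVolumeSet, bounds: tuple = DEFAULT_BOUNDS
) -> Optional[tuple]:
    """Volume-weighted (% small, % medium, % large); None for an empty set.

    Bin edges: small < bounds[0]; medium in [bounds[0], bounds[1]];
    large > bounds[1].
    """
    lo, hi = bounds
    if not lo < hi:
        raise InputError(f"bounds must satisfy lo < hi; got {bounds}")
    v = vset.volumes
    if v.size == 0:
        return None
    total = v.sum()
    small = v[v < lo].sum()
    medium = v[(v >= lo) & (v <= hi)].sum()
    large = v[v > hi].sum()
    return tuple(100.0 * x / total for x in (small, medium, large))


def pct_of_control(values_by_line: dict, control_label: str) -> dict:
    """Express each line's mean value as a percentage of the control-line
    mean; values may be scalars or sequences (averaged first)."""
    if control_label not in values_by_line:
        raise InputError(f"control line {control_label!r} missing")
    ctrl = float(np.mean(values_by_line[control_label]))
    if ctrl == 0:
        raise InputError("control mean is zero; percentages undefined")
    return {line: 100.0 * float(np.mean(vals)) / ctrl
            for line, vals in values_by_line.items()}


def read_volumes_csv(path) -> list:
    """Read (line, replicate, volume_um3) CSV into per-replicate sets."""
    df = pd.read_csv(path)
    required = {"line", "replicate", "volume_um3"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"volumes CSV missing columns: {sorted(missing)}")
    sets = []
    for (line, rep), grp in df.groupby(["line", "replicate"], sort=True):
        sets.append(MitoVolumeSet(
            volumes=grp["volume_um3"].to_numpy(dtype=float),
            line_label=str(line), replicate_id=str(rep),
        ))
    return sets


def fractions_frame(
    sets: Sequence[MitoVolumeSet], bounds: tuple = DEFAULT_BOUNDS
) -> pd.DataFrame:
    rows = []
    for s in sets:
        fr = volume_fractions(s, bounds)
        rows.append(dict(
            line=s.line_label, replicate=s.replicate_id,
            pct_small=fr[0] if fr else np.nan,
            pct_medium=fr[1] if fr else np.nan,
            pct_large=fr[2] if fr else np.nan,
        ))
    return pd.DataFrame(rows)
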