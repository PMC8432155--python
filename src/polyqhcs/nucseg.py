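"""Nuclear segmentation from the nuclear (channel 1) stain.

The segmentation chain is: median filter (disc, radius 3 px) -> global
intensity threshold (frozen DN or batch Otsu over the pooled histogram of
all median-filtered nuclear channels) -> hole filling -> distance-transform
watershed to split touching nuclei -> minimum-area filter -> consecutive
relabelling.  Per-nucleus geometry and the channel-2 intensity maximum under
each nucleus footprint are recorded alongside the label image.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import median as sk_median
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .errors import DegenerateHistogramError, InputError

__all__ = [
    "FieldImage",
    "NucleusRecord",
    "NuclearMask",
    "batch_otsu_threshold",
    "exhaustive_otsu",
    "median_filter_nuclear",
    "segment_nuclei",
]

#: structuring element radius for the pre-segmentation median filter (pixels)
MEDIAN_RADIUS = 3

#: default minimum accepted nucleus area (pixels); rejects noise specks
DEFAULT_MIN_AREA = 50

#: default minimum separation between watershed seed maxima (pixels);
#: should be at or below the smallest expected nucleus radius
DEFAULT_MIN_SEED_SEPARATION = 7

_MAX_DN = 65535


@dataclass
class FieldImage:
    """One multi-channel 2D microscopy field with plate metadata.

    ``channels`` has shape ``(n_channels, rows, cols)`` with 2-3 planes:
    channel index 0 is the nuclear stain, index 1 the aggregate (anti-HTT)
    stain, optional index 2 a neuronal marker.  Values are 16-bit DN.
    """

    channels: np.ndarray
    well_id: str = ""
    field_id: str = ""
    line_label: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels)
        if arr.ndim != 3 or arr.shape[0] not in (2, 3):
            raise InputError(
                f"channels must have shape (2-3, rows, cols); got {arr.shape}"
            )
        if arr.min() < 0 or arr.max() > _MAX_DN:
            raise InputError("channel values must lie in [0, 65535]")
        self.channels = arr

    @property
    def nuclear(self) -> np.ndarray:
        return self.channels[0]

    @property
    def ch2(self) -> np.ndarray:
        return self.channels[1]

    @property
    def marker(self) -> Optional[np.ndarray]:
        return self.channels[2] if self.channels.shape[0] > 2 else None

    @property
    def shape(self) -> tuple:
        return self.channels.shape[1:]


@dataclass
class NucleusRecord:
    """Per-nucleus measurements. ``is_acn``/``na_*`` are filled downstream."""

    label: int
    area: int
    centroid: tuple
    roundness: float
    mean_nuclear_intensity: float
    i_max_ch2: float
    is_acn: Optional[bool] = None
    na_count: Optional[int] = None
    na_area: Optional[int] = None
    ring_mean: Optional[float] = None


@dataclass
class NuclearMask:
    """Labeled nuclear mask plus per-nucleus records.

    Labels are consecutive positive integers starting at 1; 0 is background.
    """

    labels: np.ndarray
    threshold_used: float
    nuclei: list = dc_field(default_factory=list)

    @property
    def total_cells(self) -> int:
        return len(self.nuclei)


def median_filter_nuclear(image: np.ndarray, radius: int = MEDIAN_RADIUS) -> np.ndarray:
    """Disc median filter with reflective border handling."""
    return sk_median(np.asarray(image), footprint=disk(radius), mode="reflect")


def exhaustive_otsu(histogram: np.ndarray) -> int:
    """Otsu threshold by exhaustive search over all cut points.

    Maximizes the between-class variance over every possible cut; the
    returned threshold ``t`` assigns values ``<= t`` to the background
    class.  Ties are broken toward the lowest threshold.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    n = counts.sum()
    if n <= 0:
        raise DegenerateHistogramError("empty histogram")
    levels = np.arange(counts.size, dtype=np.float64)
    w0 = np.cumsum(counts)
    mu = np.cumsum(counts * levels)
    mu_total = mu[-1]
    w1 = n - w0
    # between-class variance for cut after each level; undefined where a
    # class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = (mu_total * w0 - mu * n) ** 2 / (w0 * w1)
    bcv = bcv[:-1]  # cut after the last level leaves foreground empty
    valid = np.isfinite(bcv)
    if not valid.any() or np.nanmax(bcv[valid]) <= 0:
        raise DegenerateHistogramError(
            "histogram has zero between-class variance at every cut"
        )
    bcv[~valid] = -np.inf
    return int(np.argmax(bcv))  # argmax returns the first (lowest) maximizer


def batch_otsu_threshold(
    fields: Sequence[FieldImage], median_radius: int = MEDIAN_RADIUS
) -> int:
    """Single Otsu threshold from the pooled histogram of a whole batch.

    All nuclear channels are median-filtered first, then their pixel
    histograms are pooled; the threshold is the exhaustive between-class
    variance maximizer over all 65536 levels (ties to lowest).
    """
    fields = list(fields)
    if not fields:
        raise InputError("batch_otsu_threshold needs at least one field")
    hist = np.zeros(_MAX_DN + 1, dtype=np.int64)
    for f in fields:
        filtered = median_filter_nuclear(f.nuclear, median_radius)
        hist += np.bincount(
            filtered.ravel().astype(np.int64), minlength=_MAX_DN + 1
        )
    return exhaustive_otsu(hist)


def _roundness(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / perimeter**2))


def segment_nuclei(
    field: FieldImage,
    threshold: float,
    min_area: int = DEFAULT_MIN_AREA,
    min_seed_separation: int = DEFAULT_MIN_SEED_SEPARATION,
    median_radius: int = MEDIAN_RADIUS,
) -> NuclearMask:
    """Segment nuclei from a field at a fixed intensity threshold.

    Pixels strictly above ``threshold`` (after median filtering) are
    foreground.  Touching nuclei are split by a watershed on the negated
    Euclidean distance transform seeded at distance-map local maxima
    separated by at least ``min_seed_separation`` pixels within each
    connected component.  Components smaller than ``min_area`` are dropped
    and labels renumbered consecutively.
    """
    if not (0 < threshold < _MAX_DN):
        raise InputError(f"threshold must lie in (0, {_MAX_DN}); got {threshold}")
    filtered = median_filter_nuclear(field.nuclear, median_radius)
    binary = filtered > threshold
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return NuclearMask(
            labels=np.zeros(field.shape, dtype=np.int32),
            threshold_used=float(threshold),
            nuclei=[],
        )

    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    cc, _ = ndi.label(binary, structure=structure)
    dist = ndi.distance_transform_edt(binary)
    markers = _seed_markers(dist, cc, min_seed_separation)
    labels = watershed(-dist, markers, mask=binary, connectivity=2)

    # size filter + consecutive relabel
    labels = _filter_relabel(labels, min_area)
    records = _measure(labels, filtered, field.ch2)
    return NuclearMask(labels=labels, threshold_used=float(threshold), nuclei=records)


def _seed_markers(dist: np.ndarray, cc: np.ndarray, min_sep: int) -> np.ndarray:
    """Watershed seeds: distance-map maxima per component, with a guaranteed
    seed for any component the peak detector misses (splitting-only rule)."""
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        dist, min_distance=max(1, int(min_sep)), labels=cc, exclude_border=False
    )
    markers = np.zeros(dist.shape, dtype=np.int32)
    seeded = set()
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
        seeded.add(int(cc[r, c]))
    next_id = len(coords) + 1
    missing = set(np.unique(cc)) - {0} - seeded
    for comp in sorted(missing):
        flat = np.where(cc.ravel() == comp, dist.ravel(), -1.0)
        pos = int(np.argmax(flat))
        markers[np.unravel_index(pos, dist.shape)] = next_id
        next_id += 1
    return markers


def _filter_relabel(labels: np.ndarray, min_area: int) -> np.ndarray:
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        if sel.sum() >= min_area:
            out[sel] = next_label
            next_label += 1
    return out


def _measure(labels: np.ndarray, nuclear_filtered: np.ndarray, ch2: np.ndarray) -> list:
    records = []
    for prop in regionprops(labels, intensity_image=nuclear_filtered):
        sel = labels == prop.label
        records.append(
            NucleusRecord(
                label=int(prop.label),
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                roundness=_roundness(prop.area, prop.perimeter),
                mean_nuclear_intensity=float(prop.intensity_mean),
                i_max_ch2=float(ch2[sel].max()),
            )
        )
    return records
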