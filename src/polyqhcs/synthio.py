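"""Synthetic input generator with exhaustive ground truth.

Produces two-channel 16-bit microscopy fields (nuclei as radially smoothed
discs, intra-nuclear and extra-nuclear Gaussian puncta over a diffuse
cytoplasmic background), allelic series plates whose planted inclusion
burden rises monotonically with a per-line severity scalar and with day of
differentiation, three-phase injection OCR traces, and linear /
pseudo-first-order absorbance kinetics.  Every planted object and parameter
is returned as :class:`GroundTruth` so each downstream stage can be tested
against known truth.

All randomness in one call flows from a single integer seed through one
``numpy.random.Generator``; identical spec + seed gives bit-identical
output.  Noise is Gaussian clipped to [0, 65535]; Poisson photon noise is
deliberately omitted for simplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PlacementError
from .nucseg import FieldImage

__all__ = [
    "SynthImageSpec",
    "GroundTruth",
    "PlantedNucleus",
    "PlantedSpot",
    "SeriesEntry",
    "make_field",
    "make_allelic_series",
    "make_ocr_trace",
    "make_absorbance_trace",
    "write_field_tiff",
    "write_ground_truth_csv",
    "write_plate_layout_csv",
    "write_ocr_csv",
]

_MAX_DN = 65535
_PLACEMENT_RETRIES = 500


@dataclass(frozen=True)
class SynthImageSpec:
    """Parameters of one synthetic two/three-channel field."""

    field_shape: tuple = (512, 512)
    n_nuclei: int = 50
    touching_pair_fraction: float = 0.2
    nucleus_radius_range: tuple = (11.0, 16.0)
    nucleus_intensity_range: tuple = (8000.0, 20000.0)
    acn_fraction: float = 0.2
    spots_per_acn_range: tuple = (1, 3)
    spot_peak_range: tuple = (2500.0, 6000.0)
    spot_sigma: float = 1.5
    ena_density: int = 5
    ena_peak_range: tuple = (1800.0, 2500.0)
    cytoplasm_level: float = 500.0
    # sd 12 keeps the full-field noise range (~9 sd) below the spot-call
    # tolerance of 150 so planted counts are recoverable exactly
    noise_sd: float = 12.0
    seed: int = 0
    # optional third channel (neuronal marker); enabled when marker_level set
    marker_level: Optional[float] = None
    marker_positive_fraction: float = 1.0
    marker_acn_suppression: float = 1.0
    marker_ring_width: float = 5.0

    def validate(self) -> None:
        for name in ("touching_pair_fraction", "acn_fraction",
                     "marker_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]; got {v}")
        if self.nucleus_radius_range[0] <= 0 or self.spot_sigma <= 0:
            raise InputError("radii and spot_sigma must be strictly positive")
        if self.n_nuclei < 0 or self.ena_density < 0:
            raise InputError("counts must be non-negative")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        lo, hi = self.spots_per_acn_range
        if lo < 1 or hi < lo:
            raise InputError("spots_per_acn_range must be a range with lo >= 1")


@dataclass(frozen=True)
class PlantedNucleus:
    nucleus_id: int
    center: tuple  # (row, col), float
    radius: float
    base_intensity: float
    is_touching_pair_member: bool
    is_acn: bool = False
    is_marker_positive: bool = True


@dataclass(frozen=True)
class PlantedSpot:
    parent_nucleus_id: Optional[int]  # None for extra-nuclear spots
    center: tuple
    peak_dn: float  # planted pre-noise peak value at the spot center


@dataclass
class GroundTruth:
    """Everything planted in one synthetic artifact."""

    nuclei: list = dc_field(default_factory=list)
    nuclear_spots: list = dc_field(default_factory=list)
    extra_nuclear_spots: list = dc_field(default_factory=list)
    trace_params: Optional[dict] = None
    kinetic_params: Optional[dict] = None

    @property
    def n_acn(self) -> int:
        return sum(1 for n in self.nuclei if n.is_acn)

    @property
    def acn_fraction_planted(self) -> Optional[float]:
        if not self.nuclei:
            return None
        return self.n_acn / len(self.nuclei)

    def spots_of(self, nucleus_id: int) -> list:
        return [s for s in self.nuclear_spots if s.parent_nucleus_id == nucleus_id]


# --------------------------------------------------------------------------
# image synthesis
# --------------------------------------------------------------------------

def _place_centers(spec: SynthImageSpec, rng: np.random.Generator):
    """Place nucleus centers: singles well apart, touching pairs at
    1.2-1.6 x radius so thresholding yields a fused blob with a neck."""
    h, w = spec.field_shape
    rmin, rmax = spec.nucleus_radius_range
    margin = rmax + 4.0
    n_pairs = int(round(spec.n_nuclei * spec.touching_pair_fraction / 2.0))
    n_singles = spec.n_nuclei - 2 * n_pairs
    placed = []  # (row, col, radius, pair_member)

    def far_enough(r, c, rad):
        for pr, pc, prad, _ in placed:
            if math.hypot(r - pr, c - pc) < rad + prad + 8.0:
                return False
        return True

    for _ in range(n_singles):
        rad = rng.uniform(rmin, rmax)
        for _attempt in range(_PLACEMENT_RETRIES):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if far_enough(r, c, rad):
                placed.append((r, c, rad, False))
                break
        else:
            raise PlacementError(
                f"could not place nucleus after {_PLACEMENT_RETRIES} retries"
            )
    for _ in range(n_pairs):
        rad = rng.uniform(rmin, rmax)
        sep = rng.uniform(1.2, 1.6) * rad
        for _attempt in range(_PLACEMENT_RETRIES):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            theta = rng.uniform(0, 2 * math.pi)
            r2 = r + sep * math.sin(theta)
            c2 = c + sep * math.cos(theta)
            if not (margin <= r2 <= h - margin and margin <= c2 <= w - margin):
                continue
            if far_enough(r, c, rad) and far_enough(r2, c2, rad):
                placed.append((r, c, rad, True))
                placed.append((r2, c2, rad, True))
                break
        else:
            raise PlacementError(
                f"could not place touching pair after {_PLACEMENT_RETRIES} retries"
            )
    return placed


def _render_disc(img: np.ndarray, center, radius: float, amplitude: float,
                 softness: float = 0.75) -> None:
    """Add a radially smoothed disc (logistic edge profile) in place."""
    h, w = img.shape
    r0, c0 = center
    ext = int(math.ceil(radius + 6 * softness))
    rlo, rhi = max(0, int(r0) - ext), min(h, int(r0) + ext + 1)
    clo, chi = max(0, int(c0) - ext), min(w, int(c0) + ext + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    d = np.hypot(rr - r0, cc - c0)
    img[rlo:rhi, clo:chi] += amplitude / (1.0 + np.exp((d - radius) / softness))


def _render_gaussian(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    h, w = img.shape
    r0, c0 = center
    ext = int(math.ceil(6 * sigma))
    rlo, rhi = max(0, int(r0) - ext), min(h, int(r0) + ext + 1)
    clo, chi = max(0, int(c0) - ext), min(w, int(c0) + ext + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    img[rlo:rhi, clo:chi] += amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _sample_in_disc(rng, center, max_r):
    theta = rng.uniform(0, 2 * math.pi)
    rad = max_r * math.sqrt(rng.uniform())
    return (center[0] + rad * math.sin(theta), center[1] + rad * math.cos(theta))


def make_field(spec: SynthImageSpec) -> tuple:
    """Render one synthetic field and its ground truth.

    Spot centers snap to integer pixel coordinates so the planted peak DN
    is exactly realized at one pixel; spots within a nucleus keep a minimum
    spacing of 4 x spot_sigma so the planted count is recoverable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_shape
    truth = GroundTruth()

    ch1 = np.zeros((h, w), dtype=np.float64)
    ch2 = np.full((h, w), float(spec.cytoplasm_level), dtype=np.float64)

    placed = _place_centers(spec, rng)
    n_acn = int(round(spec.acn_fraction * len(placed)))
    acn_ids = set(
        rng.choice(len(placed), size=n_acn, replace=False).tolist()
    ) if n_acn else set()
    n_pos = int(round(spec.marker_positive_fraction * len(placed)))
    pos_ids = set(
        rng.choice(len(placed), size=n_pos, replace=False).tolist()
    ) if placed else set()

    min_spacing = 4.0 * spec.spot_sigma
    for nid, (r, c, rad, pair) in enumerate(placed):
        base = rng.uniform(*spec.nucleus_intensity_range)
        _render_disc(ch1, (r, c), rad, base)
        is_acn = nid in acn_ids
        truth.nuclei.append(
            PlantedNucleus(
                nucleus_id=nid, center=(r, c), radius=rad, base_intensity=base,
                is_touching_pair_member=pair, is_acn=is_acn,
                is_marker_positive=nid in pos_ids,
            )
        )
        if not is_acn:
            continue
        k = int(rng.integers(spec.spots_per_acn_range[0],
                             spec.spots_per_acn_range[1] + 1))
        centers = []
        for _ in range(k):
            for _attempt in range(_PLACEMENT_RETRIES):
                pt = _sample_in_disc(rng, (r, c), max(0.5, rad - 4.0))
                pt = (float(round(pt[0])), float(round(pt[1])))
                if all(math.hypot(pt[0] - q[0], pt[1] - q[1]) >= min_spacing
                       for q in centers):
                    centers.append(pt)
                    break
        if len(centers) < k:
            # deterministic ring fallback so the planted count is guaranteed
            centers = []
            ring_r = min(rad - 4.0,
                         min_spacing / (2.0 * math.sin(math.pi / max(k, 2))) + 1.0
                         ) if k > 1 else 0.0
            for j in range(k):
                ang = 2.0 * math.pi * j / k
                centers.append((float(round(r + ring_r * math.sin(ang))),
                                float(round(c + ring_r * math.cos(ang)))))
        for pt in centers:
            peak = rng.uniform(*spec.spot_peak_range)
            _render_gaussian(ch2, pt, spec.spot_sigma, peak - spec.cytoplasm_level)
            truth.nuclear_spots.append(
                PlantedSpot(parent_nucleus_id=nid, center=pt, peak_dn=peak)
            )

    # extra-nuclear puncta, kept clear of all nucleus footprints
    ena_centers = []
    for _ in range(spec.ena_density):
        for _attempt in range(_PLACEMENT_RETRIES):
            r = float(round(rng.uniform(6, h - 6)))
            c = float(round(rng.uniform(6, w - 6)))
            if any(math.hypot(r - pr, c - pc) < prad + 6.0
                   for pr, pc, prad, _ in placed):
                continue
            if any(math.hypot(r - qr, c - qc) < min_spacing
                   for qr, qc in ena_centers):
                continue
            ena_centers.append((r, c))
            break
    for (r, c) in ena_centers:
        peak = rng.uniform(*spec.ena_peak_range)
        _render_gaussian(ch2, (r, c), spec.spot_sigma, peak - spec.cytoplasm_level)
        truth.extra_nuclear_spots.append(
            PlantedSpot(parent_nucleus_id=None, center=(r, c), peak_dn=peak)
        )

    channels = [ch1, ch2]
    if spec.marker_level is not None:
        ch3 = np.full((h, w), 0.05 * spec.marker_level, dtype=np.float64)
        for n in truth.nuclei:
            if not n.is_marker_positive:
                continue
            amp = spec.marker_level
            if n.is_acn:
                amp *= spec.marker_acn_suppression
            _render_disc(ch3, n.center, n.radius + spec.marker_ring_width, amp)
        channels.append(ch3)

    if spec.noise_sd > 0:
        for ch in channels:
            ch += rng.normal(0.0, spec.noise_sd, size=ch.shape)
    stack = np.clip(np.rint(np.stack(channels)), 0, _MAX_DN).astype(np.uint16)
    field = FieldImage(channels=stack)
    return field, truth


# --------------------------------------------------------------------------
# allelic series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesEntry:
    field: FieldImage
    truth: GroundTruth
    line_label: str
    day: int
    well_id: str
    severity: float
    planted_acn_fraction: float
    planted_spots_per_acn: int


def make_allelic_series(
    template: SynthImageSpec,
    lines: Sequence[str],
    days: Sequence[int],
    severities: Optional[dict] = None,
    wells_per_line: int = 16,
) -> list:
    """Plate of fields whose planted inclusion burden is monotone
    non-decreasing in per-line severity and in day.

    ``severities`` maps each line label to a scalar >= 0 (default: the
    line's index in ``lines``).  Severity 0 plants no inclusions at any
    day.  Planted ACN fraction scales as ``template.acn_fraction *
    (severity / max severity) * (day / max day)`` and spots per ACN ramp
    from 1 up to the template range maximum along the same product, both
    deterministic so the monotone structure is exact by construction.
    """
    lines = list(lines)
    days = list(days)
    if not lines or not days:
        raise InputError("lines and days must be non-empty")
    if severities is None:
        severities = {line: float(i) for i, line in enumerate(lines)}
    for line in lines:
        if line not in severities:
            raise InputError(f"no severity assigned to line {line!r}")
        if severities[line] < 0:
            raise InputError("severities must be >= 0")
    max_sev = max(severities[line] for line in lines)
    max_day = max(days)
    spots_hi = template.spots_per_acn_range[1]

    entries = []
    idx = 0
    for li, line in enumerate(lines):
        sev = severities[line]
        snorm = sev / max_sev if max_sev > 0 else 0.0
        for day in days:
            dnorm = day / max_day if max_day > 0 else 1.0
            frac = template.acn_fraction * snorm * dnorm
            k = 1 + int(round((spots_hi - 1) * snorm * dnorm)) if frac > 0 else 1
            for wi in range(wells_per_line):
                spec = replace(
                    template,
                    acn_fraction=frac,
                    spots_per_acn_range=(k, k),
                    seed=template.seed + 100003 * idx,
                )
                field, truth = make_field(spec)
                well = f"{line}_D{day:02d}_W{wi:02d}"
                field.well_id = well
                field.field_id = f"{well}_F00"
                field.line_label = line
                field.day = int(day)
                entries.append(
                    SeriesEntry(
                        field=field, truth=truth, line_label=line, day=int(day),
                        well_id=well, severity=sev, planted_acn_fraction=frac,
                        planted_spots_per_acn=k,
                    )
                )
                idx += 1
    return entries


# --------------------------------------------------------------------------
# OCR traces
# --------------------------------------------------------------------------

def make_ocr_trace(
    true_params: dict,
    n_cycles_per_phase: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    well_id: str = "W00",
    line_label: str = "",
    cell_density: float = 30000.0,
    cycle_minutes: float = 6.5,
):
    """Four-phase OCR trace whose noiseless plateaus invert the respiratory
    parameter formulas exactly.

    ``true_params`` needs keys ``non_mito``, ``basal``, ``atp_production``,
    ``proton_leak``, ``maximal`` (all >= 0, with basal = atp_production +
    proton_leak).  Plateau levels: baseline = non_mito + basal; after
    oligomycin = non_mito + proton_leak; after FCCP = non_mito + maximal;
    after rotenone/antimycin A = non_mito.
    """
    from .respirometry import OCRTrace, PHASES

    p = {k: float(true_params[k])
         for k in ("non_mito", "basal", "atp_production", "proton_leak", "maximal")}
    for k, v in p.items():
        if v < 0:
            raise InputError(f"true rate {k} must be >= 0; got {v}")
    if abs(p["basal"] - (p["atp_production"] + p["proton_leak"])) > 1e-9:
        raise InputError(
            "inconsistent true parameters: identity "
            "basal = atp_production + proton_leak is violated "
            f"({p['basal']} != {p['atp_production']} + {p['proton_leak']})"
        )
    if n_cycles_per_phase < 1:
        raise InputError("n_cycles_per_phase must be >= 1")
    levels = {
        "baseline": p["non_mito"] + p["basal"],
        "oligomycin": p["non_mito"] + p["proton_leak"],
        "fccp": p["non_mito"] + p["maximal"],
        "rot_aa": p["non_mito"],
    }
    rng = np.random.default_rng(seed)
    measurements = []
    t = 0.0
    for phase in PHASES:
        for cyc in range(n_cycles_per_phase):
            val = levels[phase]
            if noise_sd > 0:
                val += rng.normal(0.0, noise_sd)
            measurements.append((phase, cyc, t, val))
            t += cycle_minutes
    return OCRTrace(
        well_id=well_id, line_label=line_label,
        measurements=measurements, cell_density=float(cell_density),
    )


# --------------------------------------------------------------------------
# absorbance traces
# --------------------------------------------------------------------------

def make_absorbance_trace(kind: str, params: dict, seed: int = 0):
    """Synthetic absorbance time course.

    ``kind='linear'``: A(t) = intercept + slope*t (+ noise); ``params``
    may declare ``direction`` ('increase'/'decrease') which the slope sign
    must match.  ``kind='first_order'``: optional non-enzymatic linear
    segment of slope ``bg_slope`` on [0, t_switch), then an exponential
    approach to plateau with rate ``k`` per minute (amplitude
    ``amplitude``), with the linear background continuing throughout.
    """
    from .enzymology import AbsorbanceTrace

    rng = np.random.default_rng(seed)
    noise_sd = float(params.get("noise_sd", 0.0))
    n_points = int(params.get("n_points", 61))
    duration = float(params.get("duration", 5.0))
    times = np.linspace(0.0, duration, n_points)

    if kind == "linear":
        slope = float(params["slope"])
        direction = params.get("direction")
        if direction == "decrease" and slope > 0:
            raise InputError("declared direction 'decrease' but slope > 0")
        if direction == "increase" and slope < 0:
            raise InputError("declared direction 'increase' but slope < 0")
        absorbance = float(params.get("intercept", 1.0)) + slope * times
        segments = {"assay": (0.0, duration)}
        kinetic = {"kind": "linear", "slope": slope}
    elif kind == "first_order":
        k = float(params["k"])
        if k <= 0:
            raise InputError(f"first-order rate constant must be > 0; got {k}")
        amplitude = float(params.get("amplitude", 0.5))
        bg_slope = float(params.get("bg_slope", 0.0))
        a0 = float(params.get("a0", 0.1))
        t_switch = float(params.get("t_switch", 0.0))
        absorbance = a0 + bg_slope * times
        enz = times >= t_switch
        absorbance = absorbance + np.where(
            enz, amplitude * (1.0 - np.exp(-k * (times - t_switch))), 0.0
        )
        segments = {"enzymatic": (t_switch, duration)}
        if t_switch > 0:
            segments["non_enzymatic"] = (0.0, t_switch)
        kinetic = {"kind": "first_order", "k": k, "amplitude": amplitude,
                   "bg_slope": bg_slope, "t_switch": t_switch}
    else:
        raise InputError(f"unknown trace kind {kind!r}")

    if noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=absorbance.shape)
    trace = AbsorbanceTrace(
        times=times, absorbance=absorbance,
        wavelength=float(params.get("wavelength", 600.0)),
        extinction_coeff=float(params.get("extinction_coeff", 21000.0)),
        path_length=float(params.get("path_length", 1.0)),
        protein=float(params.get("protein", 1.0)),
        segments=segments,
    )
    return trace, kinetic


# --------------------------------------------------------------------------
# writers (text-first formats; TIFF only for the image stacks themselves)
# --------------------------------------------------------------------------

def write_field_tiff(field: FieldImage, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), field.channels, photometric="minisblack")


def write_ground_truth_csv(truth: GroundTruth, field_id: str, path) -> None:
    rows = []
    for n in truth.nuclei:
        rows.append(dict(object="nucleus", field_id=field_id, id=n.nucleus_id,
                         row=n.center[0], col=n.center[1], radius=n.radius,
                         amplitude=n.base_intensity, is_acn=n.is_acn,
                         pair_member=n.is_touching_pair_member))
    for s in truth.nuclear_spots:
        rows.append(dict(object="nuclear_spot", field_id=field_id,
                         id=s.parent_nucleus_id, row=s.center[0],
                         col=s.center[1], radius=np.nan, amplitude=s.peak_dn,
                         is_acn=np.nan, pair_member=np.nan))
    for s in truth.extra_nuclear_spots:
        rows.append(dict(object="extra_nuclear_spot", field_id=field_id,
                         id=-1, row=s.center[0], col=s.center[1],
                         radius=np.nan, amplitude=s.peak_dn, is_acn=np.nan,
                         pair_member=np.nan))
    pd.DataFrame(rows).to_csv(path, index=False)


def write_plate_layout_csv(entries: Sequence[SeriesEntry], path) -> None:
    pd.DataFrame(
        [dict(well=e.well_id, line=e.line_label, day=e.day,
              severity=e.severity) for e in entries]
    ).to_csv(path, index=False)


def write_ocr_csv(traces, path) -> None:
    rows = []
    for tr in traces:
        for phase, cyc, t, ocr in tr.measurements:
            rows.append(dict(well=tr.well_id, line=tr.line_label, phase=phase,
                             cycle=cyc, time=t, ocr=ocr,
                             density=tr.cell_density))
    pd.DataFrame(rows).to_csv(path, index=False)
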