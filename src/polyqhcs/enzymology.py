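"""Spectrophotometric enzyme kinetics -> specific activities and ratios.

Linear assays (complex I, II, II+III surrogate, citrate synthase) convert a
least-squares absorbance slope to nmol/min/mg via Beer-Lambert; the complex
III style assay fits a pseudo-first-order rate constant k after removing a
fitted non-enzymatic linear rate.  Activities are normalized to citrate
synthase (and CoQ10 level to CS) to correct for mitochondrial content.

Unit bookkeeping for the Beer-Lambert conversion: a slope in AU/min over a
path of ``path_length`` cm with molar extinction ``epsilon`` (M^-1 cm^-1)
is a concentration rate slope/(epsilon*path) in mol/L/min; multiplying by
the reaction volume in litres gives mol/min, x1e9 gives nmol/min, divided
by the mg protein in the reaction gives nmol/min/mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import FitQualityError, InputError

__all__ = [
    "AbsorbanceTrace",
    "ActivityResult",
    "linear_rate",
    "beer_lambert_activity",
    "inhibitor_sensitive_rate",
    "first_order_k",
    "cs_normalize",
]


@dataclass
class AbsorbanceTrace:
    """Absorbance time course with labeled analysis segments.

    ``segments`` maps a label (e.g. ``pre_inhibitor``, ``non_enzymatic``)
    to a ``(start_time, end_time)`` interval in minutes, end-inclusive.
    """

    times: np.ndarray
    absorbance: np.ndarray
    wavelength: float
    extinction_coeff: float
    path_length: float
    protein: float
    segments: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise InputError("times and absorbance must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if min(self.extinction_coeff, self.path_length, self.protein) <= 0:
            raise InputError(
                "extinction_coeff, path_length and protein must be > 0"
            )

    def segment(self, label: str) -> tuple:
        if label not in self.segments:
            raise InputError(f"trace has no segment {label!r}")
        t0, t1 = self.segments[label]
        sel = (self.times >= t0) & (self.times <= t1)
        if sel.sum() < 2:
            raise InputError(f"segment {label!r} holds fewer than 2 points")
        return self.times[sel], self.absorbance[sel]


@dataclass
class ActivityResult:
    sample_id: str
    assay: str
    specific_activity: Optional[float]  # nmol/min/mg or k/min/mg
    cs_ratio: Optional[float] = None
    coq10_cs_ratio: Optional[float] = None
    error: Optional[str] = None


def linear_rate(trace: AbsorbanceTrace, segment: str = "assay") -> float:
    """Least-squares absorbance slope (AU/min) over one labeled segment."""
    t, a = trace.segment(segment)
    return float(stats.linregress(t, a).slope)


def beer_lambert_activity(
    slope: float,
    extinction_coeff: float,
    path_length: float,
    protein_mg: float,
    volume_ml: float = 1.0,
) -> float:
    """Specific activity in nmol/min/mg from an absorbance slope.

    ``protein_mg`` is the protein mass in the reaction; ``volume_ml`` the
    reaction volume (default 1 mL cuvette).
    """
    if min(extinction_coeff, path_length, protein_mg, volume_ml) <= 0:
        raise InputError("extinction, path, protein and volume must be > 0")
    molar_per_min = abs(slope) / (extinction_coeff * path_length)  # mol/L/min
    nmol_per_min = molar_per_min * (volume_ml / 1000.0) * 1e9
    return nmol_per_min / protein_mg


def inhibitor_sensitive_rate(
    trace: AbsorbanceTrace,
    pre_segment: str = "pre_inhibitor",
    post_segment: str = "post_inhibitor",
) -> tuple:
    """Signed inhibitor-sensitive slope |pre| - |post| (AU/min) and a flag
    set when the sensitivity comes out negative (post faster than pre)."""
    pre = abs(linear_rate(trace, pre_segment))
    post = abs(linear_rate(trace, post_segment))
    sensitive = pre - post
    return sensitive, sensitive < 0


def first_order_k(
    trace: AbsorbanceTrace,
    enzymatic_segment: str = "enzymatic",
    non_enzymatic_segment: Optional[str] = "non_enzymatic",
    per_mg: bool = True,
) -> float:
    """Pseudo-first-order rate constant (per min, per mg when ``per_mg``).

    The non-enzymatic linear rate, fitted on its own segment when one is
    supplied, is subtracted from the enzymatic segment; the corrected
    course is fitted as A(t) = A_inf - (A_inf - A0) exp(-k (t - t0)) with
    A_inf, A0 and k free (joint plateau estimate, robust to truncated
    traces).
    """
    t, a = trace.segment(enzymatic_segment)
    if non_enzymatic_segment is not None and non_enzymatic_segment in trace.segments:
        bg = linear_rate(trace, non_enzymatic_segment)
        a = a - bg * t
    t0 = t[0]
    a0_guess, ainf_guess = a[0], a[-1]
    amp_guess = ainf_guess - a0_guess
    if abs(amp_guess) < 1e-12:
        raise FitQualityError("no enzymatic amplitude in corrected trace")
    # quality gate: the corrected approach must be monotone beyond noise
    diffs = np.diff(a) * np.sign(amp_guess)
    span = abs(amp_guess)
    if np.any(diffs < -0.25 * span):
        raise FitQualityError("corrected trace is non-monotone beyond noise")

    half = a0_guess + 0.5 * amp_guess
    crossing = np.nonzero((a - half) * np.sign(amp_guess) >= 0)[0]
    k_guess = (np.log(2.0) / max(t[crossing[0]] - t0, 1e-6)
               if crossing.size else 1.0)

    def model(tt, ainf, a0, k):
        return ainf - (ainf - a0) * np.exp(-k * (tt - t0))

    popt, _ = optimize.curve_fit(
        model, t, a, p0=(ainf_guess + 0.05 * amp_guess, a0_guess, k_guess),
        maxfev=20000,
    )
    k = float(abs(popt[2]))
    return k / trace.protein if per_mg else k


def cs_normalize(
    activities: dict,
    cs_activity: float,
    coq10_level: Optional[float] = None,
    sample_id: str = "",
) -> list:
    """Normalize a panel of activities (and optionally a CoQ10 level,
    pmol/mg) to citrate synthase activity.

    Returns one :class:`ActivityResult` per assay; with CS activity <= 0
    every ratio is missing and carries an error record instead.
    """
    results = []
    cs_ok = cs_activity is not None and cs_activity > 0
    err = None if cs_ok else "citrate synthase activity is not positive"
    for assay, act in activities.items():
        results.append(ActivityResult(
            sample_id=sample_id, assay=assay, specific_activity=act,
            cs_ratio=(act / cs_activity if cs_ok and act is not None else None),
            error=err,
        ))
    if coq10_level is not None:
        results.append(ActivityResult(
            sample_id=sample_id, assay="coq10", specific_activity=None,
            coq10_cs_ratio=(coq10_level / cs_activity if cs_ok else None),
            error=err,
        ))
    return results
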