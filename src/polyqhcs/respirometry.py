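"""Mito Stress Test parameter extraction from OCR traces.

Parameter definitions (phase-scoped extrema, ties to the earliest cycle):

* non-mitochondrial respiration = minimum rate after rotenone/antimycin A
* basal respiration            = last rate before first injection - non-mito
* maximal respiration          = maximum rate after FCCP - non-mito
* proton leak                  = minimum rate after oligomycin - non-mito
* ATP production               = last rate before oligomycin - minimum rate
  after oligomycin
* coupling efficiency          = 100 x ATP production / basal respiration

so basal = ATP production + proton leak holds identically.  Negative
derived rates (possible with noise) are preserved and flagged, never
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, StructuralError

__all__ = [
    "PHASES",
    "OCRTrace",
    "RespProfile",
    "density_normalize",
    "derive_parameters",
    "normalize_to_control",
    "read_ocr_csv",
    "profiles_frame",
    "line_summary",
]

PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")


@dataclass
class OCRTrace:
    """Injection-annotated OCR time series for one well.

    ``measurements`` is an ordered list of ``(phase, cycle, time, ocr)``
    tuples with phases appearing in Mito Stress order.
    """

    well_id: str
    line_label: str
    measurements: list
    cell_density: float

    def __post_init__(self) -> None:
        if self.cell_density <= 0:
            raise InputError(
                f"cell_density must be > 0; got {self.cell_density}"
            )
        seen = [phase for phase, *_ in self.measurements]
        present = [p for p in PHASES if p in seen]
        # phases must appear contiguously and in canonical order
        compact = [seen[0]] if seen else []
        for p in seen[1:]:
            if p != compact[-1]:
                compact.append(p)
        if compact != present or present != [p for p in PHASES if p in present]:
            raise StructuralError(f"phases out of order: {compact}")
        for phase, cyc, t, ocr in self.measurements:
            if not np.isfinite(ocr):
                raise InputError("OCR values must be finite")

    def phase_values(self, phase: str) -> list:
        return [ocr for ph, cyc, t, ocr in self.measurements if ph == phase]


@dataclass
class RespProfile:
    """Six derived respiratory parameters for one well."""

    well_id: str
    line_label: str
    non_mito: float
    basal: float
    maximal: float
    proton_leak: float
    atp_production: float
    coupling_efficiency: Optional[float]
    negative_flags: list = dc_field(default_factory=list)
    pct_of_control: dict = dc_field(default_factory=dict)

    RATE_FIELDS = ("non_mito", "basal", "maximal", "proton_leak",
                   "atp_production")


def density_normalize(traces: Sequence[OCRTrace]) -> list:
    """Divide every OCR value by its well's density normalized to the
    lowest density in the batch; the minimum-density well is unchanged."""
    traces = list(traces)
    if not traces:
        raise InputError("density_normalize needs at least one trace")
    min_density = min(tr.cell_density for tr in traces)
    out = []
    for tr in traces:
        factor = tr.cell_density / min_density
        out.append(replace(
            tr,
            measurements=[(ph, cyc, t, ocr / factor)
                          for ph, cyc, t, ocr in tr.measurements],
        ))
    return out


def derive_parameters(trace: OCRTrace) -> RespProfile:
    """Compute the six Mito Stress parameters for one trace."""
    for phase in PHASES:
        if not trace.phase_values(phase):
            raise StructuralError(f"missing phase: {phase}")
    baseline = trace.phase_values("baseline")
    oligo = trace.phase_values("oligomycin")
    fccp = trace.phase_values("fccp")
    rot_aa = trace.phase_values("rot_aa")

    non_mito = float(min(rot_aa))
    last_baseline = float(baseline[-1])
    min_oligo = float(min(oligo))
    basal = last_baseline - non_mito
    maximal = float(max(fccp)) - non_mito
    proton_leak = min_oligo - non_mito
    atp_production = last_baseline - min_oligo
    coupling = 100.0 * atp_production / basal if basal != 0 else None

    flags = [name for name, val in
             [("non_mito", non_mito), ("basal", basal), ("maximal", maximal),
              ("proton_leak", proton_leak), ("atp_production", atp_production)]
             if val < 0]
    return RespProfile(
        well_id=trace.well_id, line_label=trace.line_label,
        non_mito=non_mito, basal=basal, maximal=maximal,
        proton_leak=proton_leak, atp_production=atp_production,
        coupling_efficiency=coupling, negative_flags=flags,
    )


def normalize_to_control(
    profiles: Sequence[RespProfile], control_label: str
) -> list:
    """Express each rate as a percentage of the control-line mean; a rate
    whose control mean is zero is reported missing for every well."""
    profiles = list(profiles)
    control = [p for p in profiles if p.line_label == control_label]
    if not control:
        raise InputError(f"no profile carries control label {control_label!r}")
    means = {f: float(np.mean([getattr(p, f) for p in control]))
             for f in RespProfile.RATE_FIELDS}
    for p in profiles:
        p.pct_of_control = {
            f: (100.0 * getattr(p, f) / means[f] if means[f] != 0 else None)
            for f in RespProfile.RATE_FIELDS
        }
    return profiles


# --------------------------------------------------------------------------
# IO / tables
# --------------------------------------------------------------------------

def read_ocr_csv(path) -> list:
    """Read tidy OCR CSV (well, line, phase, cycle, time, ocr, density)."""
    df = pd.read_csv(path)
    required = {"well", "line", "phase", "cycle", "time", "ocr", "density"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"OCR CSV missing columns: {sorted(missing)}")
    traces = []
    for (well, line), grp in df.groupby(["well", "line"], sort=True):
        grp = grp.sort_values(["time", "cycle"], kind="stable")
        density = grp["density"].iloc[0]
        traces.append(OCRTrace(
            well_id=str(well), line_label=str(line),
            measurements=[(row.phase, int(row.cycle), float(row.time),
                           float(row.ocr)) for row in grp.itertuples()],
            cell_density=float(density),
        ))
    return traces


def profiles_frame(profiles: Sequence[RespProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = dict(well_id=p.well_id, line_label=p.line_label,
                   non_mito=p.non_mito, basal=p.basal, maximal=p.maximal,
                   proton_leak=p.proton_leak, atp_production=p.atp_production,
                   coupling_efficiency=p.coupling_efficiency,
                   negative_flags=";".join(p.negative_flags))
        for f, v in p.pct_of_control.items():
            row[f"{f}_pct_ctrl"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def line_summary(profiles: Sequence[RespProfile]) -> pd.DataFrame:
    """Per-line mean and SEM across wells for each rate and its % of
    control (SEM across wells; cross-experiment SEM is the caller's choice
    of grouping)."""
    df = profiles_frame(profiles)
    value_cols = [c for c in df.columns
                  if c not in ("well_id", "line_label", "negative_flags")]
    rows = []
    for line, grp in df.groupby("line_label", sort=True):
        row = {"line_label": line, "n_wells": len(grp)}
        for c in value_cols:
            vals = grp[c].dropna().to_numpy(dtype=float)
            row[f"{c}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{c}_sem"] = (vals.std(ddof=1) / np.sqrt(vals.size)
                               if vals.size > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
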