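"""End-to-end pipeline driver over a synthetic or on-disk plate.

All outputs are plain CSV/JSON and deterministic for a fixed config: the
run log records parameters, library versions and input hashes but no
timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .. import incquant, mitomorph, nucseg, respirometry, synthio
from ..errors import InputError
from .config import StudyConfig

__all__ = ["run_pipeline", "simulate_plate", "analyze_plate"]


def simulate_plate(config: StudyConfig) -> list:
    """Demo allelic-series plate from the config's line/day/well grid."""
    if not config.lines or not config.days:
        raise InputError("config must name at least one line and one day")
    template = synthio.SynthImageSpec(
        field_shape=config.field_shape,
        n_nuclei=config.n_nuclei,
        seed=config.seed,
    )
    severities = {line: float(i) for i, line in enumerate(config.lines)}
    return synthio.make_allelic_series(
        template, list(config.lines), list(config.days),
        severities=severities, wells_per_line=config.wells_per_line,
    )


def analyze_plate(entries, config: StudyConfig) -> dict:
    """Segment + quantify every field; pool wells; summarize lines."""
    if config.threshold_mode == "batch-otsu":
        threshold = nucseg.batch_otsu_threshold([e.field for e in entries])
    else:
        threshold = config.nuclear_threshold

    nucleus_rows = []
    field_quants = []
    well_meta = {}
    for e in entries:
        mask = nucseg.segment_nuclei(
            e.field, threshold,
            min_area=config.min_nucleus_area,
            min_seed_separation=config.min_seed_separation,
        )
        fq = incquant.quantify_field(
            mask, e.field.ch2,
            well_id=e.well_id, field_id=e.field.field_id,
            acn_threshold=config.acn_threshold,
            spot_tolerance=config.spot_tolerance,
            total_tolerance=config.total_tolerance,
            area_threshold=config.area_threshold,
            background_cutoff=config.background_cutoff,
            all_nuclei_denominator=config.na_area_all_nuclei_denominator,
        )
        field_quants.append(fq)
        well_meta[e.well_id] = (e.line_label, e.day)
        for rec in mask.nuclei:
            nucleus_rows.append(dict(
                well_id=e.well_id, field_id=e.field.field_id,
                line=e.line_label, day=e.day, label=rec.label,
                area=rec.area, centroid_row=rec.centroid[0],
                centroid_col=rec.centroid[1], roundness=rec.roundness,
                mean_nuclear_intensity=rec.mean_nuclear_intensity,
                i_max_ch2=rec.i_max_ch2, is_acn=rec.is_acn,
                na_count=rec.na_count, na_area=rec.na_area,
            ))

    wells = incquant.pool_wells(field_quants)
    well_df = incquant.well_metrics_frame(wells)
    well_df.insert(1, "line", [well_meta[w][0] for w in well_df["well_id"]])
    well_df.insert(2, "day", [well_meta[w][1] for w in well_df["well_id"]])

    metric_cols = [c for c in well_df.columns
                   if c not in ("well_id", "line", "day")]
    line_df = (well_df.groupby(["line", "day"], sort=True)[metric_cols]
               .mean(numeric_only=True).reset_index())
    return {
        "threshold": float(threshold),
        "per_nucleus": pd.DataFrame(nucleus_rows),
        "per_well": well_df,
        "per_line": line_df,
    }


def _respirometry_demo(config: StudyConfig) -> pd.DataFrame:
    """Synthetic Mito Stress plate: derive parameters and % of control."""
    rng = np.random.default_rng(config.seed + 1)
    traces = []
    scale = {line: 1.0 - 0.25 * i / max(1, len(config.lines) - 1)
             for i, line in enumerate(config.lines)}
    for line in config.lines:
        for w in range(10):
            atp, leak = 60.0 * scale[line], 20.0 * scale[line]
            params = dict(non_mito=20.0, basal=atp + leak,
                          atp_production=atp, proton_leak=leak,
                          maximal=160.0 * scale[line])
            traces.append(synthio.make_ocr_trace(
                params, n_cycles_per_phase=3, noise_sd=2.0,
                seed=int(rng.integers(0, 2**31)),
                well_id=f"{line}_R{w:02d}", line_label=line,
                cell_density=float(rng.uniform(25000, 35000)),
            ))
    traces = respirometry.density_normalize(traces)
    profiles = [respirometry.derive_parameters(t) for t in traces]
    respirometry.normalize_to_control(profiles, config.lines[0])
    return respirometry.profiles_frame(profiles)


def _mito_demo(config: StudyConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed + 2)
    sets = []
    for i, line in enumerate(config.lines):
        for rep in range(3):
            # heavier lines shift volume mass upward
            vols = rng.lognormal(mean=2.0 + 0.8 * i, sigma=1.2, size=300)
            sets.append(mitomorph.MitoVolumeSet(
                volumes=vols, line_label=line, replicate_id=f"R{rep}"
            ))
    return mitomorph.fractions_frame(sets, config.volume_bounds)


def run_pipeline(config: StudyConfig, include_extras: bool = True) -> dict:
    """Simulate, segment, quantify and summarize; write the result bundle.

    Writes per_nucleus.csv, per_well.csv, per_line.csv (plus respirometry
    and mitochondrial demo tables when ``include_extras``) and a
    machine-readable run log under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    entries = simulate_plate(config)
    results = analyze_plate(entries, config)

    results["per_nucleus"].to_csv(out / "per_nucleus.csv", index=False)
    results["per_well"].to_csv(out / "per_well.csv", index=False)
    results["per_line"].to_csv(out / "per_line.csv", index=False)
    synthio.write_plate_layout_csv(entries, out / "plate_layout.csv")

    if include_extras:
        resp = _respirometry_demo(config)
        resp.to_csv(out / "respirometry.csv", index=False)
        mito = _mito_demo(config)
        mito.to_csv(out / "mito_volumes.csv", index=False)
        results["respirometry"] = resp
        results["mito_volumes"] = mito

    config_blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    log = {
        "config": config.to_dict(),
        "threshold_used": results["threshold"],
        "n_fields": len(entries),
        "input_hash": hashlib.sha256(config_blob).hexdigest(),
        "versions": _versions(),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["run_log"] = log
    return results


def _versions() -> dict:
    import scipy
    import skimage

    from .. import __version__

    return {
        "polyqhcs": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
    }
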