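"""Readers and writers for the package's file formats.

Formats are deliberately plain: cohort tables as UTF-8 CSV with dot
decimals and the standard parameter names in the header, pore-diameter
distributions as two-column CSV, per-measurement results as JSON, RF frames
as HDF5 (see :mod:`cortbs.frames`).  Every emitted file is re-readable by
the package's own readers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference_cohort as ref
from .errors import SchemaError
from .pore_morphology import PoreDiameterDistribution, PoreMetrics
from .spectral_estimation import AttenuationResult, BSCResult

MANDATORY_COLUMNS = [
    "subject_id", "group", "sex",
    "fracture_any", "fracture_vertebral", "fracture_other",
    "age", "height_cm", "weight_kg", "bmi",
]

_NUMERIC_MANDATORY = ["age", "height_cm", "weight_kg", "bmi"]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table, validating the dialect and schema.

    Missing mandatory columns and comma-decimal numbers are rejected with a
    schema error (never silently misparsed); unknown columns are preserved
    with a warning; column order in the file is irrelevant beyond being kept.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file is missing mandatory columns: {missing}")
    numeric_cols = _NUMERIC_MANDATORY + [
        c for c in df.columns if c in ref.DXA_PARAMS or c in ref.CORTBS_PARAMS
    ]
    for col in numeric_cols:
        if df[col].dtype == object:
            sample = df[col].astype(str).str.contains(r"^\s*-?\d+,\d+\s*$")
            if sample.any():
                raise SchemaError(
                    f"column {col!r} uses comma decimals; the cohort dialect "
                    "requires dot decimals"
                )
            raise SchemaError(f"column {col!r} is not numeric")
    known = set(MANDATORY_COLUMNS) | set(ref.ALL_PARAMS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown cohort columns preserved: {unknown}", stacklevel=2)
    for col in ("fracture_any", "fracture_vertebral", "fracture_other"):
        df[col] = df[col].astype(bool)
    return df


def write_distribution_csv(dist: PoreDiameterDistribution, path) -> None:
    pd.DataFrame({
        "diameter_um": dist.centers_um,
        "density_per_mm2": dist.counts,
    }).to_csv(path, index=False)


def read_distribution_csv(path) -> PoreDiameterDistribution:
    df = pd.read_csv(path)
    if list(df.columns) != ["diameter_um", "density_per_mm2"]:
        raise SchemaError("distribution CSV must have columns "
                          "diameter_um, density_per_mm2")
    centers = df["diameter_um"].to_numpy(dtype=float)
    width = centers[1] - centers[0]
    return PoreDiameterDistribution(centers - width / 2.0,
                                    df["density_per_mm2"].to_numpy(dtype=float))


def rf_results_to_dict(att: AttenuationResult, bsc: BSCResult,
                       qc: dict | None = None) -> dict:
    """JSON-serializable per-measurement spectral results."""
    return {
        "α_0": att.alpha0,
        "α_f": att.alphaf,
        "α_6-MHz": att.alpha6mhz,
        "BSC_Mean": bsc.bsc_mean,
        "AIB_Average": bsc.aib_average,
        "band_mhz": list(att.band),
        "fit_r2": att.fit_r2,
        "frequencies_mhz": [float(f) for f in bsc.frequencies],
        "bsc_db": [float(v) for v in bsc.bsc_db],
        "qc": qc or {},
    }


def bsc_from_dict(payload: dict) -> BSCResult:
    """Rebuild a BSC result from :func:`rf_results_to_dict` output."""
    freqs = np.asarray(payload["frequencies_mhz"], dtype=float)
    bsc_db = np.asarray(payload["bsc_db"], dtype=float)
    return BSCResult(
        frequencies=freqs,
        bsc_db=bsc_db,
        bsc_mean=float(payload["BSC_Mean"]),
        aib_average=float(payload["AIB_Average"]),
        band=tuple(payload["band_mhz"]),
    )


def metrics_to_dict(metrics: PoreMetrics, att: AttenuationResult | None = None,
                    bsc: BSCResult | None = None) -> dict:
    """Metrics block keyed by the standard parameter names."""
    out = metrics.as_dict()
    if att is not None:
        out["α_0"] = att.alpha0
        out["α_f"] = att.alphaf
        out["α_6-MHz"] = att.alpha6mhz
    if bsc is not None:
        out["BSC_Mean"] = bsc.bsc_mean
        out["AIB_Average"] = bsc.aib_average
    return out


def write_json(payload: dict, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=True),
        encoding="utf-8",
    )


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
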