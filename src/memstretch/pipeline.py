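"""Reproducible pipeline glue: reference replication, aggregation, manifests.

`reference_report` re-derives the published characterization of the
reference stretch device from the model alone (no external data): the
calibrated membrane solution and its culture-region statistics, plus the
circular-statistics identities linking the published alignment indices to
their circular standard deviations and relative change.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .membrane import CultureRegion, GridSpec, MembraneModel, MembraneSpec, Metric
from .orientation import circular_sd, relative_change

__all__ = [
    "REFERENCE_MEMBRANE",
    "REFERENCE_ALIGNMENT",
    "reference_report",
    "aggregate_conditions",
    "write_manifest",
]

#: Published characterization of the reference device (membrane mechanics).
REFERENCE_MEMBRANE = {
    "max_deflection_um": 839.0,
    "deflection_to_thickness": 4.19,
    "mean_vm_percent": 14.2,
    "cv_percent": 18.7,
    "uniformity_percent": 81.3,
    "min_vm_percent": 9.9,
    "max_vm_percent": 17.9,
    "grid_variation_limit_percent": 2.0,
}

#: Published alignment indices (static control vs cyclic stretch) and the
#: dispersion / change statistics they imply.
REFERENCE_ALIGNMENT = {
    "R_static": 0.387,
    "R_stretch": 0.501,
    "circ_sd_static_deg": 78.9,
    "circ_sd_stretch_deg": 67.3,
    "relative_change_percent": 29.5,
}


def reference_report(
    model: MembraneModel | None = None,
    target_avg_strain: float = 0.10,
    membrane_rtol: float = 0.05,
    identity_atol: float = 0.1,
) -> pd.DataFrame:
    """Computed-vs-published comparison table for the reference device.

    Membrane rows are compared at ``membrane_rtol`` relative tolerance
    (default 5 %, reflecting the shape-function and averaging-metric
    ambiguity of the published description); circular-statistics identities
    at ``identity_atol`` absolute (the printed precision, 0.1).  The table is
    deterministic: nothing in it is sampled.
    """
    model = model or MembraneModel()
    res = model.fit(target_avg_strain=target_avg_strain)
    rep = res.report

    rows = []

    def mrow(name, computed, reference):
        ok = abs(computed - reference) <= membrane_rtol * abs(reference)
        rows.append(
            dict(
                quantity=name,
                computed=computed,
                reference=reference,
                tolerance=f"±{membrane_rtol:.0%} rel",
                status="pass" if ok else "FAIL",
            )
        )

    mrow("max deflection (um)", res.w0 * 1e6, REFERENCE_MEMBRANE["max_deflection_um"])
    mrow(
        "deflection/thickness",
        res.deflection_to_thickness,
        REFERENCE_MEMBRANE["deflection_to_thickness"],
    )
    mrow("region mean von Mises (%)", 100 * rep.mean_strain, REFERENCE_MEMBRANE["mean_vm_percent"])
    mrow("region CV (%)", rep.cv_percent, REFERENCE_MEMBRANE["cv_percent"])
    mrow("uniformity (%)", rep.uniformity_percent, REFERENCE_MEMBRANE["uniformity_percent"])
    mrow("region min strain (%)", 100 * rep.min_strain, REFERENCE_MEMBRANE["min_vm_percent"])
    mrow("region max strain (%)", 100 * rep.max_strain, REFERENCE_MEMBRANE["max_vm_percent"])

    gv = 100 * res.grid_variation()
    rows.append(
        dict(
            quantity="grid variation in peak strain (%)",
            computed=gv,
            reference=REFERENCE_MEMBRANE["grid_variation_limit_percent"],
            tolerance="upper bound",
            status="pass" if gv < REFERENCE_MEMBRANE["grid_variation_limit_percent"] else "FAIL",
        )
    )

    for cond, r_key, sd_key in (
        ("static", "R_static", "circ_sd_static_deg"),
        ("stretch", "R_stretch", "circ_sd_stretch_deg"),
    ):
        computed = circular_sd(REFERENCE_ALIGNMENT[r_key])
        ref = REFERENCE_ALIGNMENT[sd_key]
        rows.append(
            dict(
                quantity=f"circular SD, {cond} (deg)",
                computed=computed,
                reference=ref,
                tolerance=f"±{identity_atol} abs",
                status="pass" if abs(computed - ref) <= identity_atol else "FAIL",
            )
        )
    rc = relative_change(REFERENCE_ALIGNMENT["R_static"], REFERENCE_ALIGNMENT["R_stretch"])
    rows.append(
        dict(
            quantity="alignment relative change (%)",
            computed=rc,
            reference=REFERENCE_ALIGNMENT["relative_change_percent"],
            tolerance=f"±{identity_atol} abs",
            status=(
                "pass"
                if abs(rc - REFERENCE_ALIGNMENT["relative_change_percent"]) <= identity_atol
                else "FAIL"
            ),
        )
    )
    df = pd.DataFrame(rows)
    df.attrs["metric"] = model.metric.value
    df.attrs["profile"] = model.profile
    df.attrs["membrane_strain"] = model.membrane_strain
    return df


def aggregate_conditions(results: dict[str, dict]) -> pd.DataFrame:
    """Per-condition summary table from heterogeneous stage results.

    ``results`` maps a condition label to a dict that may hold any of the
    orientation statistics (``R``, ``mean_axis``, ``circ_sd``) and strain
    quantities (``avg_strain``, ``green_xx``, ``green_yy``,
    ``residual_rms``).  Missing fields stay missing (NaN), never zero.
    """
    if not results:
        raise ValueError("no condition results supplied")
    cols = ["R", "mean_axis", "circ_sd", "avg_strain", "green_xx", "green_yy", "residual_rms"]
    rows = []
    for name, res in results.items():
        row = {"condition": name}
        for c in cols:
            if res is not None and c in res:
                row[c] = res[c]
        rows.append(row)
    return pd.DataFrame(rows).reindex(columns=["condition", *cols])


def write_manifest(outdir: str | Path, config: dict, seed: int | None = None) -> Path:
    """Record the fully-resolved configuration of a run for reproducibility."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "memstretch",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": _jsonable(config),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
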