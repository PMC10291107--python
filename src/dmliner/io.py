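"""File formats: scan CSV with a YAML metadata sidecar, per-point deviation
export, and the JSON assessment report.

Scan CSV dialect: header ``trace_id,azimuth_deg,x_mm,y_mm,z_mm`` (plus an
optional ``true_dev_um`` column for simulated scans), points ordered from
the pole to the trace terminus within each trace. Coordinates are written
as shortest round-trip decimal text, so write-then-read reproduces the
point arrays bit for bit. The sidecar (``<scan>.meta.yaml`` by default)
records the surface side, nominal geometry, protocol and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deviation import DeviationField, RegionLabel, RepeatabilityReport, SummaryStats
from .fitting import ReferenceSphere
from .scan import SurfaceScan
from .specs import LinerSpec, ProtocolSpec

__all__ = [
    "write_scan",
    "read_scan",
    "write_deviations",
    "build_report",
    "write_report",
    "read_report",
    "validate_report",
    "REPORT_SCHEMA_VERSION",
]

SCAN_COLUMNS = ["trace_id", "azimuth_deg", "x_mm", "y_mm", "z_mm"]
REPORT_SCHEMA_VERSION = "1.0"


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(csv_path.suffix + ".meta.yaml")


def write_scan(
    scan: SurfaceScan,
    csv_path,
    include_ground_truth: bool = False,
    sidecar_path=None,
) -> Path:
    """Write a scan as CSV plus YAML metadata sidecar."""
    csv_path = Path(csv_path)
    cols = {
        "trace_id": scan.trace_index,
        "azimuth_deg": scan.azimuths[scan.trace_index],
        "x_mm": scan.points[:, 0],
        "y_mm": scan.points[:, 1],
        "z_mm": scan.points[:, 2],
    }
    if include_ground_truth:
        if scan.true_dev_um is None:
            raise ValueError("scan has no ground truth to export")
        cols["true_dev_um"] = scan.true_dev_um
    # default float formatting is shortest repr -> lossless round trip
    pd.DataFrame(cols).to_csv(csv_path, index=False)

    meta = {
        "format": "dmliner-scan",
        "format_version": "1.0",
        "side": scan.side,
        "liner": {
            "internal_diameter_mm": scan.liner.internal_diameter,
            "external_diameter_mm": scan.liner.external_diameter,
            "bore_polar_angle_deg": scan.liner.bore_polar_angle,
            "external_overrun_mm": scan.liner.external_overrun,
        },
        "protocol": {
            "azimuth_step_deg": scan.protocol.azimuth_step,
            "point_pitch_mm": scan.protocol.point_pitch,
            "rim_exclusion_mm": scan.protocol.rim_exclusion,
        },
        "provenance": scan.provenance,
    }
    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(csv_path)
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return csv_path


def read_scan(csv_path, sidecar_path=None) -> SurfaceScan:
    """Read a scan CSV and its metadata sidecar; raises informative parse
    errors naming the offending header or row."""
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else _sidecar_path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(f"scan file not found: {csv_path}")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed scan header in {csv_path.name}: missing column(s) "
            f"{', '.join(missing)} (expected {','.join(SCAN_COLUMNS)})"
        )
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(coords), axis=1)
    if bad.any():
        row = int(np.argmax(bad)) + 2  # 1-based, after header
        raise ValueError(f"non-finite coordinate at {csv_path.name} row {row}")

    meta = yaml.safe_load(sidecar.read_text())
    liner = LinerSpec(
        internal_diameter=meta["liner"]["internal_diameter_mm"],
        external_diameter=meta["liner"]["external_diameter_mm"],
        bore_polar_angle=meta["liner"]["bore_polar_angle_deg"],
        external_overrun=meta["liner"]["external_overrun_mm"],
    )
    protocol = ProtocolSpec(
        azimuth_step=meta["protocol"]["azimuth_step_deg"],
        point_pitch=meta["protocol"]["point_pitch_mm"],
        rim_exclusion=meta["protocol"]["rim_exclusion_mm"],
    )
    trace_ids = df["trace_id"].to_numpy(dtype=int)
    # nominal azimuth per trace, order of first appearance
    _, first = np.unique(trace_ids, return_index=True)
    first = np.sort(first)
    azimuths = df["azimuth_deg"].to_numpy(dtype=float)[first]
    diffs = np.diff(azimuths)
    if np.any(diffs <= 0):
        row = int(first[int(np.argmax(diffs <= 0)) + 1]) + 2  # 1-based incl. header
        raise ValueError(
            f"trace azimuths not strictly increasing at {csv_path.name} row {row}"
        )
    true_dev = (
        df["true_dev_um"].to_numpy(dtype=float) if "true_dev_um" in df.columns else None
    )
    provenance = dict(meta.get("provenance") or {})
    provenance.setdefault("source_file", str(csv_path))
    return SurfaceScan(
        side=meta["side"],
        points=coords,
        trace_index=trace_ids,
        azimuths=azimuths,
        liner=liner,
        protocol=protocol,
        provenance=provenance,
        true_dev_um=true_dev,
    )


def write_deviations(field: DeviationField, scan: SurfaceScan, csv_path) -> Path:
    """Export the per-point deviation field as scan CSV plus
    polar/azimuth/deviation columns."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "trace_id": scan.trace_index,
            "azimuth_deg": scan.azimuths[scan.trace_index],
            "x_mm": scan.points[:, 0],
            "y_mm": scan.points[:, 1],
            "z_mm": scan.points[:, 2],
            "polar_deg": field.polar_deg,
            "azimuth_fit_deg": field.azimuth_deg,
            "dev_um": field.dev_um,
        }
    ).to_csv(csv_path, index=False)
    return csv_path


# --- assessment report -------------------------------------------------

# required key -> type (a minimal published schema; validated on read/write)
_REPORT_SCHEMA = {
    "schema_version": str,
    "tool_version": str,
    "scan": dict,
    "reference": dict,
    "summary": dict,
    "regions": list,
    "artifacts": dict,
    "config": dict,
}


def validate_report(report: dict) -> dict:
    for key, typ in _REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    return report


def build_report(
    scan: SurfaceScan,
    reference: ReferenceSphere,
    summary: SummaryStats,
    regions: Sequence[RegionLabel] = (),
    artifacts: Optional[dict] = None,
    config: Optional[dict] = None,
) -> dict:
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "scan": {
            "side": scan.side,
            "n_points": scan.n_points,
            "n_traces": scan.n_traces,
            "provenance": scan.provenance,
        },
        "reference": reference.to_dict(),
        "summary": summary.to_dict(),
        "regions": [r.to_dict() for r in regions],
        "artifacts": dict(artifacts or {}),
        "config": dict(config or {}),
    }
    return validate_report(report)


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(validate_report(report), indent=2, sort_keys=True))
    return path


def read_report(path) -> dict:
    return validate_report(json.loads(Path(path).read_text()))


def write_repeatability(rep: RepeatabilityReport, path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "repeatability": rep.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
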