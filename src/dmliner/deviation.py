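"""Signed geometric variance, per-scan summaries, damage-region labelling
and cross-repeat repeatability statistics.

The geometric variance of a point is its signed radial distance to the
fitted reference sphere, in micrometres, with the convention that positive
values denote penetration into the material and negative values denote
protrusion out of the reference geometry — on both the concave internal
and the convex external surface. The method quantifies dimensional change
only; it cannot distinguish wear (material loss) from deformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .fitting import ReferenceSphere
from .geometry import cartesian_to_spherical
from .scan import SurfaceScan
from .simulate import side_sign

__all__ = [
    "DeviationField",
    "SummaryStats",
    "RegionLabel",
    "RepeatabilityReport",
    "signed_deviation",
    "summarize",
    "label_regions",
    "repeatability",
]


@dataclass
class DeviationField:
    """Per-point signed geometric variance aligned to a scan.

    ``polar_deg``/``azimuth_deg`` are spherical coordinates about the
    fitted centre with the scan's polar axis; ``dev_um`` is the signed
    deviation (penetration positive).
    """

    side: str
    trace_index: np.ndarray
    point_in_trace: np.ndarray
    polar_deg: np.ndarray
    azimuth_deg: np.ndarray
    dev_um: np.ndarray
    reference: ReferenceSphere
    n_traces: int

    @property
    def n_points(self) -> int:
        return self.dev_um.size


@dataclass(frozen=True)
class SummaryStats:
    """Mean/median/min/max geometric variance of one scan, µm, plus the
    fitted reference radius (mm)."""

    mean: float
    median: float
    min: float
    max: float
    reference_radius: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "mean_um": self.mean,
            "median_um": self.median,
            "min_um": self.min,
            "max_um": self.max,
            "reference_radius_mm": self.reference_radius,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class RegionLabel:
    """A connected damaged region on the (trace x point) grid."""

    region_id: int
    polarity: str  # "penetrating" or "protruding"
    member_index: np.ndarray  # flat indices into the deviation field
    peak_dev_um: float
    n_points: int
    solid_angle_sr: float

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "polarity": self.polarity,
            "peak_dev_um": self.peak_dev_um,
            "n_points": self.n_points,
            "solid_angle_sr": self.solid_angle_sr,
        }


@dataclass(frozen=True)
class RepeatabilityReport:
    """Sample standard deviations (n-1 denominator) of the fitted radius
    and of each deviation summary across repeated measurements, µm."""

    radius_sd_um: float
    mean_sd_um: float
    median_sd_um: float
    min_sd_um: float
    max_sd_um: float
    n_repeats: int

    def to_dict(self) -> dict:
        return {
            "radius_sd_um": self.radius_sd_um,
            "mean_sd_um": self.mean_sd_um,
            "median_sd_um": self.median_sd_um,
            "min_sd_um": self.min_sd_um,
            "max_sd_um": self.max_sd_um,
            "n_repeats": self.n_repeats,
        }


def signed_deviation(scan: SurfaceScan, ref: ReferenceSphere) -> DeviationField:
    """Signed geometric variance of every scan point about the reference.

    deviation = s * (|p - c| - r) * 1000 µm, with s = +1 for the internal
    concave surface and s = -1 for the external convex surface, so that
    penetration into material is positive on both sides.
    """
    if ref.centre.shape != (3,):
        raise ValueError("reference centre must be a 3-vector")
    s = side_sign(scan.side)
    r_mm, polar, azimuth = cartesian_to_spherical(scan.points, centre=ref.centre)
    dev_um = s * (r_mm - ref.radius) * 1000.0
    return DeviationField(
        side=scan.side,
        trace_index=scan.trace_index.copy(),
        point_in_trace=scan.point_in_trace,
        polar_deg=polar,
        azimuth_deg=azimuth,
        dev_um=dev_um,
        reference=ref,
        n_traces=scan.n_traces,
    )


def summarize(field: DeviationField) -> SummaryStats:
    """Arithmetic mean, median (mean of middle two for even counts), min and
    max of the deviation field."""
    if field.n_points == 0:
        raise ValueError("cannot summarise an empty deviation field")
    d = field.dev_um
    return SummaryStats(
        mean=float(np.mean(d)),
        median=float(np.median(d)),
        min=float(np.min(d)),
        max=float(np.max(d)),
        reference_radius=float(field.reference.radius),
        n_points=int(d.size),
    )


def _merge_wrap(labels: np.ndarray) -> np.ndarray:
    """Union labels that touch across the azimuthal seam (first/last row)."""
    n_lab = labels.max()
    if n_lab == 0:
        return labels
    parent = np.arange(n_lab + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    first, last = labels[0], labels[-1]
    for a, b in zip(first, last):
        if a > 0 and b > 0:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    out = labels.copy()
    for lab in range(1, n_lab + 1):
        out[labels == lab] = find(lab)
    return out


def label_regions(
    field: DeviationField,
    threshold: float = 20.0,
    min_points: int = 5,
) -> List[RegionLabel]:
    """Label connected damaged regions of the deviation field.

    Points with deviation >= ``threshold`` µm (penetrating) or
    <= -``threshold`` (protruding) are grouped into 4-connected components
    on the (trace, point-index) grid, with azimuthal wrap-around between
    the first and last trace; components smaller than ``min_points`` are
    dropped. The solid-angle proxy integrates sin(polar) * dpolar * dazimuth
    over member points.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_rows = field.n_traces
    n_cols = int(field.point_in_trace.max()) + 1
    grid = np.full((n_rows, n_cols), np.nan)
    flat = np.full((n_rows, n_cols), -1, dtype=int)
    grid[field.trace_index, field.point_in_trace] = field.dev_um
    flat[field.trace_index, field.point_in_trace] = np.arange(field.n_points)

    # local angular cell size for the solid-angle proxy
    dphi = np.deg2rad(360.0 / n_rows)
    polar_grid = np.full((n_rows, n_cols), np.nan)
    polar_grid[field.trace_index, field.point_in_trace] = field.polar_deg
    dtheta = np.abs(np.gradient(np.deg2rad(polar_grid), axis=1))

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    regions: List[RegionLabel] = []
    rid = 0
    for polarity, mask in (
        ("penetrating", np.nan_to_num(grid, nan=0.0) >= threshold),
        ("protruding", np.nan_to_num(grid, nan=0.0) <= -threshold),
    ):
        labels, _ = ndimage.label(mask, structure=structure)
        labels = _merge_wrap(labels)
        for lab in np.unique(labels):
            if lab == 0:
                continue
            sel = labels == lab
            if sel.sum() < min_points:
                continue
            devs = grid[sel]
            peak = float(devs.max()) if polarity == "penetrating" else float(devs.min())
            sa = float(
                np.nansum(np.sin(np.deg2rad(polar_grid[sel])) * dtheta[sel] * dphi)
            )
            rid += 1
            regions.append(
                RegionLabel(
                    region_id=rid,
                    polarity=polarity,
                    member_index=flat[sel],
                    peak_dev_um=peak,
                    n_points=int(sel.sum()),
                    solid_angle_sr=sa,
                )
            )
    return regions


def repeatability(stats: Sequence[SummaryStats]) -> RepeatabilityReport:
    """Sample standard deviation (n-1) of the fitted radius and of each
    deviation summary across repeated measurements of one surface."""
    if len(stats) < 2:
        raise ValueError("repeatability needs at least 2 repeats")
    radii_um = np.array([s.reference_radius for s in stats]) * 1000.0
    sd = lambda v: float(np.std(np.asarray(v, dtype=float), ddof=1))
    return RepeatabilityReport(
        radius_sd_um=sd(radii_um),
        mean_sd_um=sd([s.mean for s in stats]),
        median_sd_um=sd([s.median for s in stats]),
        min_sd_um=sd([s.min for s in stats]),
        max_sd_um=sd([s.max for s in stats]),
        n_repeats=len(stats),
    )
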