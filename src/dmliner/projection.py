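"""Exploded-view planar projection and heatmap rendering.

A dual-mobility liner surface is supra-hemispheric: a plain top-down view
would fold points beyond the equator onto points below it. The exploded
projection keeps the true top-down layout inside the equator (planar radius
rho = r * sin(polar)) and continues beyond the equator by arc length
(rho = r * (1 + (polar - 90 deg) in radians)), which is continuous at the
equator and strictly monotone in polar angle along every meridian, so the
whole surface is visible without overlap. The equator is drawn as a black
circle of radius r. An azimuthal-equidistant alternative (rho = r * polar
in radians) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .deviation import DeviationField

__all__ = ["ProjectedPoints", "HeatmapGrid", "project", "rasterize", "render"]


@dataclass
class ProjectedPoints:
    """Planar polar coordinates of a deviation field (struct of arrays)."""

    rho_mm: np.ndarray
    azimuth_deg: np.ndarray
    dev_um: np.ndarray
    above_equator: np.ndarray
    equator_radius_mm: float

    @property
    def n_points(self) -> int:
        return self.rho_mm.size


@dataclass
class HeatmapGrid:
    """Regular polar raster of mean deviation per cell.

    ``values`` is (n_rho, n_azimuth) mean deviation µm; cells with no
    points are masked (``counts == 0``), never zero-filled. ``vmax`` is the
    symmetric diverging colour limit.
    """

    rho_edges: np.ndarray
    azimuth_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    equator_radius_mm: float
    vmax: float

    @property
    def mask(self) -> np.ndarray:
        return self.counts == 0

    def to_frame(self) -> pd.DataFrame:
        rho_c = 0.5 * (self.rho_edges[:-1] + self.rho_edges[1:])
        az_c = 0.5 * (self.azimuth_edges[:-1] + self.azimuth_edges[1:])
        rr, aa = np.meshgrid(rho_c, az_c, indexing="ij")
        return pd.DataFrame(
            {
                "rho_mm": rr.ravel(),
                "azimuth_deg": aa.ravel(),
                "dev_um": np.where(self.mask, np.nan, self.values).ravel(),
                "n_points": self.counts.ravel().astype(int),
            }
        )


def project(field: DeviationField, mode: str = "exploded") -> ProjectedPoints:
    """Project a deviation field to the plane.

    ``mode="exploded"``: top-down inside the equator, arc-length radial
    continuation beyond it. ``mode="equidistant"``: rho = r * polar(rad)
    everywhere (pure azimuthal-equidistant).
    """
    theta = np.asarray(field.polar_deg, dtype=float)
    if theta.size == 0:
        raise ValueError("deviation field has no spherical coordinates")
    r = field.reference.radius
    th_rad = np.deg2rad(theta)
    if mode == "exploded":
        rho = np.where(
            theta <= 90.0,
            r * np.sin(th_rad),
            r * (1.0 + (th_rad - np.pi / 2.0)),
        )
    elif mode == "equidistant":
        rho = r * th_rad
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return ProjectedPoints(
        rho_mm=rho,
        azimuth_deg=field.azimuth_deg.copy(),
        dev_um=field.dev_um.copy(),
        above_equator=theta > 90.0,
        equator_radius_mm=r,
    )


def rasterize(
    projected: ProjectedPoints,
    n_rho: int = 100,
    n_azimuth: int = 144,
    vmax: Optional[float] = None,
) -> HeatmapGrid:
    """Bin projected points into a polar raster of mean deviation.

    Colour limits default to max |deviation| rounded up to the next 10 µm
    (symmetric about zero).
    """
    if n_rho <= 0 or n_azimuth <= 0:
        raise ValueError("raster resolution must be positive")
    if projected.n_points == 0:
        raise ValueError("no points to rasterize")
    rho_max = float(projected.rho_mm.max())
    if rho_max <= 0:
        rho_max = projected.equator_radius_mm
    rho_edges = np.linspace(0.0, rho_max * (1 + 1e-12), n_rho + 1)
    az_edges = np.linspace(0.0, 360.0, n_azimuth + 1)
    counts, _, _ = np.histogram2d(
        projected.rho_mm, projected.azimuth_deg, bins=[rho_edges, az_edges]
    )
    sums, _, _ = np.histogram2d(
        projected.rho_mm,
        projected.azimuth_deg,
        bins=[rho_edges, az_edges],
        weights=projected.dev_um,
    )
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.where(counts == 0, 1, counts), np.nan)
    if vmax is None:
        peak = float(np.abs(projected.dev_um).max())
        vmax = max(10.0, np.ceil(peak / 10.0) * 10.0)
    return HeatmapGrid(
        rho_edges=rho_edges,
        azimuth_edges=az_edges,
        values=values,
        counts=counts.astype(int),
        equator_radius_mm=projected.equator_radius_mm,
        vmax=float(vmax),
    )


def render(
    grid: HeatmapGrid,
    image_path,
    grid_csv_path=None,
    cmap: str = "RdBu_r",
    title: Optional[str] = None,
    dpi: int = 150,
) -> Tuple[Path, Optional[Path]]:
    """Write the heatmap image and a machine-readable grid CSV.

    Penetration (positive) renders warm, protrusion cool, on a symmetric
    diverging scale; the equator is marked by a black circle. Deterministic
    for fixed inputs and style.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    image_path = Path(image_path)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 5))
    az_rad = np.deg2rad(grid.azimuth_edges)
    masked = np.ma.masked_where(grid.mask, grid.values)
    pm = ax.pcolormesh(
        az_rad,
        grid.rho_edges,
        masked,
        cmap=cmap,
        vmin=-grid.vmax,
        vmax=grid.vmax,
        shading="flat",
    )
    eq = np.linspace(0, 2 * np.pi, 361)
    ax.plot(eq, np.full_like(eq, grid.equator_radius_mm), color="black", lw=1.2)
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    ax.grid(False)
    cb = fig.colorbar(pm, ax=ax, pad=0.08)
    cb.set_label("geometric variance (µm)")
    if title:
        ax.set_title(title)
    fig.savefig(image_path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)

    csv_path = None
    if grid_csv_path is not None:
        csv_path = Path(grid_csv_path)
        grid.to_frame().to_csv(csv_path, index=False, na_rep="")
    return image_path, csv_path
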