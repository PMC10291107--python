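"""Parametric descriptions of a dual-mobility liner, the trace protocol,
surface defects and measurement noise.

All lengths are millimetres internally; defect magnitudes and deviations
are expressed in micrometres (the scale on which wear and deformation of
polyethylene bearings is reported). Angles are degrees at the API surface.

Sign convention for defect magnitude: positive = penetration into the
material (wear, gouging), negative = protrusion out of the reference
geometry (e.g. transferred or displaced material).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = [
    "LinerSpec",
    "ProtocolSpec",
    "DefectSpec",
    "NoiseSpec",
    "DEFECT_KINDS",
    "DEFECT_PROFILES",
]

DEFECT_KINDS = (
    "wear_patch",
    "gouge",
    "circular_mark",
    "polar_protrusion",
    "machining_ripple",
)
DEFECT_PROFILES = ("cosine_cap", "gaussian")


@dataclass(frozen=True)
class LinerSpec:
    """Nominal geometry of one dual-mobility polyethylene liner.

    The internal (concave, head-facing) surface is a spherical cap that
    extends past the equator to the retentive bore; the external (convex,
    shell-facing) surface extends a short way beyond the equator. The polar
    axis is +z by convention.

    Parameters
    ----------
    internal_diameter : float
        Nominal internal articulating diameter, mm.
    external_diameter : float
        Nominal external articulating diameter, mm.
    bore_polar_angle : float
        Polar angle (degrees from the pole) at which the internal spherical
        surface terminates at the retentive bore. Must be supra-hemispheric
        (> 90 deg) and < 180 deg.
    external_overrun : float
        Arc length, mm, by which external traces continue beyond the
        equator along the surface.
    """

    internal_diameter: float = 28.0
    external_diameter: float = 63.0
    bore_polar_angle: float = 100.0
    external_overrun: float = 3.0

    def __post_init__(self) -> None:
        if not (self.internal_diameter > 0 and self.external_diameter > 0):
            raise ValueError("liner diameters must be positive")
        if self.internal_diameter >= self.external_diameter:
            raise ValueError("internal diameter must be smaller than external")
        if not (90.0 < self.bore_polar_angle < 180.0):
            raise ValueError("bore polar angle must lie in (90, 180) degrees")
        if self.external_overrun < 0:
            raise ValueError("external overrun must be non-negative")

    @property
    def internal_radius(self) -> float:
        return self.internal_diameter / 2.0

    @property
    def external_radius(self) -> float:
        return self.external_diameter / 2.0

    def radius(self, side: str) -> float:
        if side == "internal_concave":
            return self.internal_radius
        if side == "external_convex":
            return self.external_radius
        raise ValueError(f"unknown surface side: {side!r}")


@dataclass(frozen=True)
class ProtocolSpec:
    """Trace-acquisition protocol: meridional traces about the polar axis.

    ``azimuth_step`` must divide 360 exactly; the trace count is derived
    from it (144 traces at the default 2.5 degree spacing). ``point_pitch``
    is the arc spacing of points along each trace, and ``rim_exclusion``
    is the width (arc mm) of the band next to the external trace end that
    is dropped before fitting and analysis.
    """

    azimuth_step: float = 2.5
    point_pitch: float = 0.3
    rim_exclusion: float = 0.0

    def __post_init__(self) -> None:
        if self.azimuth_step <= 0:
            raise ValueError("azimuth step must be positive")
        n = 360.0 / self.azimuth_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("azimuth step must divide 360 exactly")
        if self.point_pitch <= 0:
            raise ValueError("point pitch must be positive")
        if self.rim_exclusion < 0:
            raise ValueError("rim exclusion must be non-negative")

    @property
    def n_traces(self) -> int:
        return int(round(360.0 / self.azimuth_step))


@dataclass(frozen=True)
class DefectSpec:
    """One parametric radial-displacement defect on a spherical surface.

    Kinds
    -----
    wear_patch, circular_mark, polar_protrusion
        Rotationally symmetric caps centred at ``centre``; ``angular_extent``
        is the cap radius (degrees of great-circle arc).
    gouge
        A track along the great-circle segment from ``centre`` to
        ``path_end``; ``angular_extent`` is the half-width ``w`` of the
        cross-profile (degrees).
    machining_ripple
        A circumferential ripple, sinusoidal in polar angle with wavelength
        ``angular_extent`` degrees; covers the whole surface.

    ``magnitude`` is the peak displacement in micrometres; positive values
    penetrate into material, negative values protrude out of it.
    """

    kind: str
    centre: Tuple[float, float] = (0.0, 0.0)  # (polar deg, azimuth deg)
    angular_extent: float = 5.0
    magnitude: float = 50.0
    profile: str = "cosine_cap"
    path_end: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise ValueError(
                f"unknown defect kind {self.kind!r}; expected one of {DEFECT_KINDS}"
            )
        if self.profile not in DEFECT_PROFILES:
            raise ValueError(
                f"unknown defect profile {self.profile!r}; "
                f"expected one of {DEFECT_PROFILES}"
            )
        if self.angular_extent <= 0:
            raise ValueError("angular extent must be positive")
        if self.magnitude == 0:
            raise ValueError("defect magnitude must be non-zero")
        if (self.kind == "gouge") != (self.path_end is not None):
            raise ValueError("path_end must be given for gouges and only for gouges")


@dataclass(frozen=True)
class NoiseSpec:
    """Isotropic Gaussian radial measurement noise (1-sigma, micrometres)."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
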