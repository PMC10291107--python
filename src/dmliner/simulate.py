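"""Virtual coordinate-measuring machine.

Generates synthetic dual-mobility liner surface scans that follow the same
acquisition protocol as a physical CMM programme: meridional traces at a
fixed azimuthal spacing, each originating at the pole and terminating at
the retentive bore (internal surface) or a fixed arc length beyond the
equator (external surface). Parametric defects (wear patches, gouges,
circular marks, a polar protrusion, machining ripple) are imposed as radial
displacements of the surface, isotropic Gaussian radial noise emulates the
measurement noise floor, and an optional rigid-body transform emulates
refixturing of the component between repeats. Every simulated point carries
its noise-free ground-truth deviation so recovery can be tested end to end.

Sign bookkeeping: a defect displacement D > 0 means penetration into the
material. Material lies outside the internal (concave) surface and inside
the external (convex) surface, so penetration moves internal points to
larger radii and external points to smaller radii. ``side_sign`` (+1
internal, -1 external) encodes this; the signed-deviation computation in
:mod:`dmliner.deviation` uses the same factor, so the ground-truth field is
recovered with penetration positive on both sides.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .geometry import apply_rigid, spherical_to_cartesian, unit_vector, arc_segment_angle, great_circle_angle
from .scan import SurfaceScan
from .specs import DefectSpec, LinerSpec, NoiseSpec, ProtocolSpec

__all__ = [
    "side_sign",
    "radial_displacement",
    "total_displacement",
    "simulate_scan",
    "ground_truth_field",
]


def side_sign(side: str) -> float:
    """+1 for the internal concave surface, -1 for the external convex one."""
    if side == "internal_concave":
        return 1.0
    if side == "external_convex":
        return -1.0
    raise ValueError(f"unknown surface side {side!r}")


def radial_displacement(defect: DefectSpec, polar_deg, azimuth_deg) -> np.ndarray:
    """Signed displacement (µm, penetration positive) contributed by one
    defect at surface locations given as (polar, azimuth) degrees.

    Cap-like kinds (wear_patch, circular_mark, polar_protrusion) fall off
    with great-circle distance ``g`` from the cap centre:

    * ``cosine_cap``:  m * cos(pi * g / (2 * g0)) for g <= g0, else 0
    * ``gaussian``:    m * exp(-(g / g0)**2)

    Gouges use the angular distance ``d`` to the great-circle path segment
    with half-width ``w = angular_extent`` (same two profiles). Machining
    ripple is m * sin(2*pi*polar / wavelength) with the wavelength stored in
    ``angular_extent``; it covers the whole surface.
    """
    polar = np.atleast_1d(np.asarray(polar_deg, dtype=float))
    azimuth = np.atleast_1d(np.asarray(azimuth_deg, dtype=float))
    if np.any(polar < 0) or np.any(polar > 180):
        raise ValueError("polar angle must lie in [0, 180] degrees")
    m = defect.magnitude
    ext = defect.angular_extent

    if defect.kind == "machining_ripple":
        return m * np.sin(2.0 * np.pi * polar / ext)

    u = unit_vector(polar, azimuth)
    if defect.kind == "gouge":
        a = unit_vector(*defect.centre)
        b = unit_vector(*defect.path_end)
        dist = arc_segment_angle(u, a, b)
    else:  # rotationally symmetric cap
        c = unit_vector(*defect.centre)
        dist = great_circle_angle(u, c)

    if defect.profile == "gaussian":
        return m * np.exp(-((dist / ext) ** 2))
    out = np.where(dist <= ext, m * np.cos(np.pi * dist / (2.0 * ext)), 0.0)
    return out


def total_displacement(defects: Sequence[DefectSpec], polar_deg, azimuth_deg) -> np.ndarray:
    """Sum of all defect contributions (µm); additive and order-independent."""
    polar = np.atleast_1d(np.asarray(polar_deg, dtype=float))
    total = np.zeros_like(polar)
    for d in defects:
        total = total + radial_displacement(d, polar, azimuth_deg)
    return total


def _trace_polar_angles(liner: LinerSpec, side: str, protocol: ProtocolSpec) -> np.ndarray:
    r = liner.radius(side)
    if side == "internal_concave":
        theta_max = np.deg2rad(liner.bore_polar_angle)
    else:
        theta_max = np.pi / 2.0 + liner.external_overrun / r
    dtheta = protocol.point_pitch / r
    if dtheta > theta_max:
        raise ValueError("point pitch exceeds the trace arc length")
    n_steps = int(np.floor(theta_max / dtheta + 1e-12))
    return np.degrees(np.arange(n_steps + 1) * dtheta)


def simulate_scan(
    liner: LinerSpec,
    side: str,
    protocol: ProtocolSpec = ProtocolSpec(),
    defects: Sequence[DefectSpec] = (),
    noise: NoiseSpec = NoiseSpec(),
    rotation: Optional[np.ndarray] = None,
    translation: Optional[np.ndarray] = None,
) -> SurfaceScan:
    """Simulate one surface scan.

    Each of the ``protocol.n_traces`` traces samples its meridian at
    ``point_pitch`` arc spacing from the pole to the surface terminus. The
    measured radius of each point is the nominal radius, displaced by the
    summed defect field (towards/away from the centre according to the
    side), plus Gaussian radial noise; the whole cloud is then mapped
    through the rigid transform. Identical inputs and seed give identical
    output.
    """
    s = side_sign(side)
    r_nom = liner.radius(side)
    polar_1trace = _trace_polar_angles(liner, side, protocol)
    azimuths = np.arange(protocol.n_traces) * protocol.azimuth_step

    n_per = polar_1trace.size
    polar = np.tile(polar_1trace, protocol.n_traces)
    azim = np.repeat(azimuths, n_per)
    trace_index = np.repeat(np.arange(protocol.n_traces), n_per)

    dev_um = total_displacement(defects, polar, azim) if defects else np.zeros(polar.size)

    rng = np.random.default_rng(noise.seed)
    noise_um = rng.normal(0.0, noise.sigma, size=polar.size) if noise.sigma > 0 else 0.0

    radius_mm = r_nom + s * (dev_um + noise_um) / 1000.0
    points = spherical_to_cartesian(polar, azim, 1.0) * radius_mm[:, None]
    points = apply_rigid(points, rotation, translation)

    provenance = {
        "generator": "dmliner.simulate.simulate_scan",
        "seed": noise.seed,
        "sigma_um": noise.sigma,
        "n_defects": len(defects),
        "has_ground_truth": True,
        "rotated": rotation is not None,
        "translated": translation is not None,
    }
    return SurfaceScan(
        side=side,
        points=points,
        trace_index=trace_index,
        azimuths=azimuths,
        liner=liner,
        protocol=protocol,
        provenance=provenance,
        true_dev_um=dev_um,
    )


def ground_truth_field(scan: SurfaceScan) -> np.ndarray:
    """Noise-free signed deviation (µm, penetration positive) each simulated
    point was generated with; raises for scans without ground truth."""
    if scan.true_dev_um is None:
        raise ValueError("scan carries no ground-truth field")
    return scan.true_dev_um.copy()
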