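"""The SurfaceScan container: one surface's point cloud organised as
ordered meridional traces, with liner and protocol metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from .specs import LinerSpec, ProtocolSpec

__all__ = ["SurfaceScan", "SIDES"]

SIDES = ("internal_concave", "external_convex")


@dataclass
class SurfaceScan:
    """Point cloud of one articulating surface as ordered meridional traces.

    Points are stored flat; ``trace_index`` maps each point to its trace and
    within each trace points run from the pole towards the trace terminus
    (retentive bore for the internal surface, past the equator for the
    external surface).

    Attributes
    ----------
    side : str
        ``"internal_concave"`` or ``"external_convex"``.
    points : ndarray, shape (n, 3)
        Cartesian coordinates, mm.
    trace_index : ndarray, shape (n,)
        Zero-based trace id per point; non-decreasing.
    azimuths : ndarray, shape (n_traces,)
        Nominal trace azimuths in degrees, strictly increasing in [0, 360).
    liner, protocol
        Nominal geometry and acquisition protocol.
    provenance : dict
        Free-form origin record (seed, simulator options, source file).
    true_dev_um : ndarray or None
        Noise-free signed ground-truth deviation per point (penetration
        positive), present only for simulated scans.
    """

    side: str
    points: np.ndarray
    trace_index: np.ndarray
    azimuths: np.ndarray
    liner: LinerSpec
    protocol: ProtocolSpec
    provenance: Dict = field(default_factory=dict)
    true_dev_um: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown surface side {self.side!r}")
        self.points = np.asarray(self.points, dtype=float)
        self.trace_index = np.asarray(self.trace_index, dtype=int)
        self.azimuths = np.asarray(self.azimuths, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if self.points.shape[0] == 0:
            raise ValueError("scan has no points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("scan contains non-finite coordinates")
        if self.trace_index.shape != (self.points.shape[0],):
            raise ValueError("trace_index must have one entry per point")
        present = np.unique(self.trace_index)
        if present.size != self.azimuths.size or not np.array_equal(
            present, np.arange(self.azimuths.size)
        ):
            raise ValueError("every trace must be non-empty and consecutively numbered")
        if not (
            np.all(np.diff(self.azimuths) > 0)
            and self.azimuths[0] >= 0
            and self.azimuths[-1] < 360
        ):
            raise ValueError("trace azimuths must be strictly increasing in [0, 360)")
        if self.true_dev_um is not None:
            self.true_dev_um = np.asarray(self.true_dev_um, dtype=float)
            if self.true_dev_um.shape != (self.points.shape[0],):
                raise ValueError("true_dev_um must have one entry per point")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_traces(self) -> int:
        return self.azimuths.size

    @property
    def point_in_trace(self) -> np.ndarray:
        """Index of each point within its trace (0 at the pole end)."""
        idx = np.zeros(self.n_points, dtype=int)
        for t in range(self.n_traces):
            sel = self.trace_index == t
            idx[sel] = np.arange(sel.sum())
        return idx

    def iter_traces(self) -> Iterator[Tuple[int, float, np.ndarray]]:
        for t in range(self.n_traces):
            sel = self.trace_index == t
            yield t, float(self.azimuths[t]), self.points[sel]

    def nominal_radius(self) -> float:
        return self.liner.radius(self.side)
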