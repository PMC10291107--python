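"""Reference-sphere approximation of the unworn surface geometry.

Retrieved implants have no reliable pre-service dimensions, so the unworn
reference of each articulating surface is approximated by a sphere fitted
to the measured cloud. The default is orthogonal-distance (geometric)
least squares — minimising sum((|p - c| - r)^2) — solved by a damped
Gauss-Newton iteration initialised from the closed-form algebraic fit,
which is the metrology standard for this problem. A robust variant
iteratively discards gross outliers (e.g. deeply gouged regions) using a
MAD-based scale so the reference is dominated by undamaged surface.

`SphereFit` is a scikit-learn style estimator; `fit_sphere_algebraic`,
`fit_sphere_geometric` and `fit_reference` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .scan import SurfaceScan

__all__ = [
    "ReferenceSphere",
    "SphereFit",
    "fit_sphere_algebraic",
    "fit_sphere_geometric",
    "fit_reference",
    "rim_excluded_points",
]


@dataclass(frozen=True)
class ReferenceSphere:
    """Fitted unworn reference geometry and fit diagnostics.

    ``centre`` is in mm, ``radius`` in mm, residual summaries in µm
    (orthogonal radial residuals |p - c| - r).
    """

    centre: np.ndarray
    radius: float
    rms_residual: float
    max_abs_residual: float
    n_points: int
    n_iterations: int
    converged: bool

    def __post_init__(self):
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")
        if self.n_points < 4:
            raise ValueError("a sphere fit needs at least 4 points")

    def residuals_mm(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return np.linalg.norm(p - self.centre, axis=1) - self.radius

    def to_dict(self) -> dict:
        d = asdict(self)
        d["centre"] = [float(v) for v in self.centre]
        return d


def _validate_points(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if p.shape[0] < 4:
        raise ValueError("sphere fitting needs at least 4 points")
    if not np.all(np.isfinite(p)):
        raise ValueError("points contain non-finite values")
    return p


def _diagnostics(p, centre, radius, n_iterations, converged) -> ReferenceSphere:
    res_mm = np.linalg.norm(p - centre, axis=1) - radius
    return ReferenceSphere(
        centre=centre,
        radius=float(radius),
        rms_residual=float(np.sqrt(np.mean(res_mm**2)) * 1000.0),
        max_abs_residual=float(np.max(np.abs(res_mm)) * 1000.0),
        n_points=p.shape[0],
        n_iterations=n_iterations,
        converged=converged,
    )


def fit_sphere_algebraic(points) -> ReferenceSphere:
    """Closed-form linear least-squares sphere.

    Solves min sum((|p|^2 - 2 p.c - rho)^2) for (c, rho) and recovers
    radius = sqrt(rho + |c|^2). Deterministic, non-iterative; used as the
    initialiser for the geometric fit.
    """
    p = _validate_points(points)
    A = np.column_stack([2.0 * p, np.ones(p.shape[0])])
    b = np.sum(p * p, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError(
            "degenerate point configuration (coplanar or lower-dimensional); "
            "cannot determine a sphere"
        )
    centre = sol[:3]
    rho = sol[3]
    r2 = rho + centre @ centre
    if r2 <= 0:
        raise ValueError("degenerate point configuration: non-positive fitted radius")
    return _diagnostics(p, centre, np.sqrt(r2), 0, True)


def fit_sphere_geometric(
    points,
    init: Optional[ReferenceSphere] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ReferenceSphere:
    """Orthogonal-distance sphere fit by damped Gauss-Newton.

    Minimises sum((|p - c| - r)^2). Each Gauss-Newton step is halved until
    the residual sum does not increase, so the fit never ends worse than
    its initialiser. Convergence is declared when the centre and radius
    updates are both below ``tol`` (mm); otherwise the result is returned
    with ``converged=False``.
    """
    p = _validate_points(points)
    if init is None:
        init = fit_sphere_algebraic(p)
    c = init.centre.astype(float).copy()
    r = float(init.radius)

    def sse(c_, r_):
        return float(np.sum((np.linalg.norm(p - c_, axis=1) - r_) ** 2))

    current = sse(c, r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        diff = p - c
        d = np.linalg.norm(diff, axis=1)
        d = np.where(d < 1e-15, 1e-15, d)
        f = d - r
        J = np.empty((p.shape[0], 4))
        J[:, :3] = -diff / d[:, None]
        J[:, 3] = -1.0
        step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        lam = 1.0
        while lam > 1e-10:
            c_new = c + lam * step[:3]
            r_new = r + lam * step[3]
            new = sse(c_new, r_new)
            if new <= current or not np.isfinite(new):
                break
            lam *= 0.5
        if r_new <= 0:
            raise ValueError("degenerate input: geometric fit collapsed to r <= 0")
        moved = max(float(np.max(np.abs(lam * step[:3]))), abs(lam * step[3]))
        c, r, current = c_new, r_new, new
        if moved < tol:
            converged = True
            break
    return _diagnostics(p, c, r, it, converged)


class SphereFit(BaseEstimator):
    """Scikit-learn style estimator for the unworn reference sphere.

    Parameters
    ----------
    method : {"geometric", "algebraic"}
        Orthogonal-distance Gauss-Newton fit (default) or the closed-form
        algebraic fit alone.
    tol : float
        Convergence tolerance on centre/radius updates, mm.
    max_iter : int
        Gauss-Newton iteration cap.
    robust : bool
        Iteratively refit after discarding points whose absolute orthogonal
        residual exceeds ``robust_k * 1.4826 * MAD`` of the residuals, until
        the inlier set is stable or ``robust_max_rounds`` rounds.
    robust_k : float
    robust_max_rounds : int

    Attributes (after ``fit``)
    --------------------------
    centre_ : ndarray (3,), mm
    radius_ : float, mm
    rms_residual_um_, max_abs_residual_um_ : float
    n_iterations_ : int
    converged_ : bool
    n_points_ : int   (points actually used, after any trimming)
    inlier_mask_ : ndarray of bool over the input points
    result_ : ReferenceSphere
    """

    def __init__(
        self,
        method: str = "geometric",
        tol: float = 1e-6,
        max_iter: int = 100,
        robust: bool = False,
        robust_k: float = 3.0,
        robust_max_rounds: int = 10,
    ):
        self.method = method
        self.tol = tol
        self.max_iter = max_iter
        self.robust = robust
        self.robust_k = robust_k
        self.robust_max_rounds = robust_max_rounds

    def _fit_once(self, p: np.ndarray) -> ReferenceSphere:
        if self.method == "algebraic":
            return fit_sphere_algebraic(p)
        if self.method == "geometric":
            return fit_sphere_geometric(p, tol=self.tol, max_iter=self.max_iter)
        raise ValueError(f"unknown fit method {self.method!r}")

    def fit(self, X, y=None):
        p = _validate_points(X)
        mask = np.ones(p.shape[0], dtype=bool)
        ref = self._fit_once(p)
        if self.robust:
            for _ in range(self.robust_max_rounds):
                res = ref.residuals_mm(p)
                med = np.median(res[mask])
                scale = 1.4826 * np.median(np.abs(res[mask] - med))
                if scale <= 0:
                    break
                new_mask = np.abs(res) <= self.robust_k * scale
                if new_mask.sum() < 4:
                    raise ValueError("robust trimming removed too many points")
                if np.array_equal(new_mask, mask):
                    break
                mask = new_mask
                ref = self._fit_once(p[mask])
        self.inlier_mask_ = mask
        self.result_ = ref
        self.centre_ = ref.centre
        self.radius_ = ref.radius
        self.rms_residual_um_ = ref.rms_residual
        self.max_abs_residual_um_ = ref.max_abs_residual
        self.n_iterations_ = ref.n_iterations
        self.converged_ = ref.converged
        self.n_points_ = ref.n_points
        return self

    def predict(self, X) -> np.ndarray:
        """Signed orthogonal distance (mm) of points to the fitted sphere."""
        if not hasattr(self, "result_"):
            raise AttributeError("SphereFit is not fitted yet")
        return self.result_.residuals_mm(np.asarray(X, dtype=float))


def rim_excluded_points(scan: SurfaceScan, rim_exclusion: Optional[float] = None) -> np.ndarray:
    """Boolean mask keeping points outside the excluded rim band.

    On the external surface, points whose along-trace arc distance from the
    trace end is below ``rim_exclusion`` (mm, default from the scan
    protocol) are dropped, emulating the thin band near the external rim
    that cannot be probed reliably. Internal scans are returned unmasked.
    """
    if rim_exclusion is None:
        rim_exclusion = scan.protocol.rim_exclusion
    keep = np.ones(scan.n_points, dtype=bool)
    if scan.side != "external_convex" or rim_exclusion <= 0:
        return keep
    for t, _, pts in scan.iter_traces():
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        from_end = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
        keep[scan.trace_index == t] = from_end >= rim_exclusion
    return keep


def fit_reference(
    scan: SurfaceScan,
    robust: bool = False,
    robust_k: float = 3.0,
    robust_max_rounds: int = 10,
    rim_exclusion: Optional[float] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ReferenceSphere:
    """Fit the unworn reference sphere to a scan (rim exclusion applied on
    the external side, then pooled geometric fit, optionally robust)."""
    keep = rim_excluded_points(scan, rim_exclusion)
    if not keep.any():
        raise ValueError("rim exclusion removed every point")
    est = SphereFit(
        method="geometric",
        tol=tol,
        max_iter=max_iter,
        robust=robust,
        robust_k=robust_k,
        robust_max_rounds=robust_max_rounds,
    )
    est.fit(scan.points[keep])
    return est.result_
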