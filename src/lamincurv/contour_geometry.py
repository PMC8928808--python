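"""Curvature estimation on nuclear contours via osculating-circle fits.

Contours are ordered 2-D point lists in micrometres.  Local curvature at a
boundary point is estimated by least-squares fitting a circle — the
"osculating circle" or circle of best fit — to the points within a 2 um arc
window centred on the query point, and reporting the inverse fitted radius.
Pore and pipette curvatures are simply the inverse of the pore/pipette
radius, i.e. ``2 / diameter``.

Sign convention: curvature is positive where the contour bulges outward
(convex); concave and saddle regions carry negative sign.  A 2-D contour
yields one principal curvature; the second (out-of-plane) curvature must be
supplied, or assumed equal at a pole of revolution, to classify the sign of
the Gaussian curvature with :func:`gaussian_sign`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

__all__ = [
    "Contour",
    "CurvatureSample",
    "PoreSpec",
    "CurvatureRegime",
    "GaussianSign",
    "CurvatureEstimationError",
    "osculating_curvature",
    "curvature_profile",
    "classify_regime",
    "gaussian_sign",
    "pore_curvature",
]


class CurvatureEstimationError(ValueError):
    """Raised when a contour window is too degenerate for a circle fit."""


class CurvatureRegime(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    UNSET = "unset"


class GaussianSign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    PARABOLIC = "parabolic"


@dataclass
class Contour:
    """Ordered boundary points (x, y) in um.

    Closed contours are normalised to counter-clockwise orientation at
    construction, so that convex-outward curvature is positive everywhere.
    ``metadata`` carries optional generator annotations (analytic pole
    curvature etc.) and is not interpreted here.
    """

    points: np.ndarray
    closed: bool = True
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("points must be an (N, 2) array with N >= 2")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour points must be finite")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive contour points must be distinct")
        if self.closed and len(pts) >= 3:
            # shoelace signed area; reverse clockwise input to enforce CCW
            x, y = pts[:, 0], pts[:, 1]
            area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
            if area < 0:
                pts = pts[::-1].copy()
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def segment_lengths(self) -> np.ndarray:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    @property
    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        seg = self.segment_lengths
        return np.concatenate([[0.0], np.cumsum(seg)])[: self.n_points]

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())


@dataclass
class CurvatureSample:
    """Signed curvature at an arc position, with optional regime label."""

    arc_position: float
    curvature_kappa: float
    regime: CurvatureRegime = CurvatureRegime.UNSET


@dataclass(frozen=True)
class PoreSpec:
    """A migration pore or aspiration pipette characterised by its diameter."""

    diameter_D: float

    def __post_init__(self) -> None:
        if not self.diameter_D > 0:
            raise ValueError(f"diameter must be positive, got {self.diameter_D}")

    @property
    def radius_Rpip(self) -> float:
        return self.diameter_D / 2.0

    @property
    def curvature(self) -> float:
        return 2.0 / self.diameter_D


def pore_curvature(diameter: float) -> float:
    """Imposed curvature of a pore/pipette: inverse radius, ``2 / diameter``."""
    if not diameter > 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    return 2.0 / diameter


def _kasa_circle(pts: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle: returns (cx, cy, r)."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    return float(cx), float(cy), float(np.sqrt(max(r2, 0.0)))


def _geometric_step(pts: np.ndarray, cx: float, cy: float, r: float) -> tuple[float, float, float]:
    """One Gauss-Newton step on the geometric (orthogonal-distance) objective."""
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    d = np.hypot(dx, dy)
    if np.any(d == 0):
        return cx, cy, r
    J = np.column_stack([-dx / d, -dy / d, -np.ones(len(d))])
    step, *_ = np.linalg.lstsq(J, -(d - r), rcond=None)
    return cx + float(step[0]), cy + float(step[1]), r + float(step[2])


def _curvature_at_arc(
    contour: Contour, s0: float, arc_window: float, adaptive: bool = True
) -> float:
    """Signed osculating-circle curvature at arc position ``s0``."""
    pts = contour.points
    arc = contour.arc_positions
    total = contour.arc_length

    # signed arc offset of every point from s0 (wrapping for closed contours)
    if contour.closed:
        offset = ((arc - s0 + total / 2) % total) - total / 2
    else:
        offset = arc - s0
    order = np.argsort(offset, kind="stable")

    def window_points(window: float) -> np.ndarray:
        sel = order[np.abs(offset[order]) <= window / 2 + 1e-12]
        return sel

    sel = window_points(arc_window)
    if len(sel) < 3:
        raise CurvatureEstimationError(
            f"arc window {arc_window} um holds {len(sel)} points (< 3) at s={s0:.3g}"
        )

    scale = max(total, 1.0)
    window = arc_window
    kappa_mag = 0.0
    # Shrink the window so the fitted arc subtends at most ~1/2 radian of the
    # osculating circle: a fixed window wider than the local radius averages
    # over varying curvature and underestimates sharp poles.
    for _ in range(6 if adaptive else 1):
        w = pts[sel]
        # collinearity guard: straight segments have infinite radius
        chord = w[-1] - w[0]
        chord_len = np.linalg.norm(chord)
        if chord_len == 0:
            raise CurvatureEstimationError("window degenerates to a single location")
        t = chord / chord_len
        offsets_perp = (w - w[0]) @ np.array([-t[1], t[0]])
        if np.max(np.abs(offsets_perp)) < 1e-9 * scale:
            return 0.0
        cx, cy, r = _kasa_circle(w)
        cx, cy, r = _geometric_step(w, cx, cy, r)
        if not np.isfinite(r) or r <= 0 or r > 1e9 * scale:
            return 0.0
        kappa_mag = 1.0 / r
        if not adaptive:
            break
        new_window = min(arc_window, max(0.5 * r, 1e-6))
        if new_window >= window - 1e-12:
            break
        new_sel = window_points(new_window)
        if len(new_sel) < 5:
            # keep at least the 5 nearest points so the fit stays overdetermined
            nearest = np.argsort(np.abs(offset), kind="stable")[: min(5, len(arc))]
            new_sel = nearest[np.argsort(offset[nearest], kind="stable")]
        if len(new_sel) < 3 or np.array_equal(new_sel, sel):
            break
        sel, window = new_sel, new_window

    # sign from local convexity: cross product of window-half chords, CCW positive
    w = pts[sel]
    i_mid = int(np.argmin(np.abs(offset[sel])))
    u = w[i_mid] - w[0]
    v = w[-1] - w[i_mid]
    if i_mid == 0 or i_mid == len(w) - 1:
        u = w[-1] - w[0]
        v = u
    cross = u[0] * v[1] - u[1] * v[0]
    sign = 1.0 if cross >= 0 else -1.0
    return sign * kappa_mag


def osculating_curvature(
    contour: Contour, index: int, arc_window: float = 2.0, adaptive: bool = True
) -> float:
    """Signed curvature (1/um) at a contour point from an osculating-circle fit.

    A circle is least-squares fitted (algebraic fit refined by one geometric
    Gauss-Newton step) to the contour points within an arc window of total
    length ``arc_window`` centred on point ``index``; the magnitude of the
    returned curvature is the inverse fitted radius, the sign is positive for
    convex-outward (CCW) bulges.  Straight segments return exactly 0.

    With ``adaptive=True`` (default) the window is iteratively shrunk so the
    fitted arc subtends at most half a radian of the fitted circle, which
    removes the averaging bias at features sharper than the nominal window
    while leaving constant-curvature arcs untouched.

    The window is capped at half the contour's arc length, so small nuclei
    (perimeter below 4 um) are fitted over at most half their boundary.

    Raises
    ------
    CurvatureEstimationError
        If fewer than 3 points fall inside the nominal window.
    ValueError
        If ``arc_window`` is non-positive.
    """
    if contour.n_points < 8:
        raise CurvatureEstimationError(
            f"curvature estimation needs >= 8 contour points, got {contour.n_points}"
        )
    if not arc_window > 0:
        raise ValueError(f"arc_window must be positive, got {arc_window}")
    if not 0 <= index < contour.n_points:
        raise IndexError(f"index {index} out of range for {contour.n_points} points")
    window = min(arc_window, contour.arc_length / 2)
    return _curvature_at_arc(contour, contour.arc_positions[index], window, adaptive)


def curvature_profile(
    contour: Contour, spacing: float, arc_window: float = 2.0, adaptive: bool = True
) -> list[CurvatureSample]:
    """Curvature sampled at equal arc-length spacing around the contour.

    Samples sit at arc positions ``0, spacing, 2*spacing, ...`` so roughly
    ``arc_length / spacing`` samples are produced; each is an
    osculating-circle estimate with the same window rules as
    :func:`osculating_curvature`.  Regimes are left ``UNSET`` — assign them
    explicitly with :func:`classify_regime`.
    """
    if not spacing > 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if contour.n_points < 8:
        raise CurvatureEstimationError(
            f"curvature estimation needs >= 8 contour points, got {contour.n_points}"
        )
    total = contour.arc_length
    last = total if contour.closed else total + spacing / 2
    positions = np.arange(0.0, last, spacing)
    if not contour.closed:
        positions = positions[positions <= total]
    return [
        CurvatureSample(float(s), _curvature_at_arc(contour, float(s), arc_window, adaptive))
        for s in positions
    ]


def classify_regime(kappa: float, thresholds: tuple[float, float]) -> CurvatureRegime:
    """Assign a curvature magnitude to the low / medium / high regime.

    ``thresholds = (low_hi, med_hi)``: curvature below ``low_hi`` is low,
    in ``[low_hi, med_hi)`` medium, at or above ``med_hi`` high — boundaries
    are assigned upward.  Negative (concave) curvature is classified low with
    a warning, since concave sites are not rupture-prone in the model.
    """
    low_hi, med_hi = thresholds
    if not 0 < low_hi < med_hi:
        raise ValueError(f"thresholds must satisfy 0 < low_hi < med_hi, got {thresholds}")
    if kappa < 0:
        warnings.warn(
            f"negative (concave) curvature {kappa:.3g} classified as low regime",
            stacklevel=2,
        )
        return CurvatureRegime.LOW
    if kappa < low_hi:
        return CurvatureRegime.LOW
    if kappa < med_hi:
        return CurvatureRegime.MEDIUM
    return CurvatureRegime.HIGH


def gaussian_sign(kappa1: float, kappa2: float) -> GaussianSign:
    """Sign class of the Gaussian curvature ``kappa1 * kappa2``.

    Positive (cap/pole, both principal curvatures same sign) is the regime
    where curvature-driven lamina dilution applies; negative is a saddle such
    as the cusp where a pipette wall meets the nuclear surface; parabolic
    covers cylinder sides where one principal curvature vanishes.
    """
    prod = kappa1 * kappa2
    if prod > 0:
        return GaussianSign.POSITIVE
    if prod < 0:
        return GaussianSign.NEGATIVE
    return GaussianSign.PARABOLIC
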