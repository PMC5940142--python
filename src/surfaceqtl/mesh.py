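"""Mesh-point construction on response surfaces.

Two mesh flavors discretize a surface for different purposes:

* the **absolute mesh** anchors points at the intersections of fixed-z
  contours with rays fanned at fixed angles about a surface-specific
  *local axis* through the peak — it samples the central, best-determined
  region of a surface in absolute (xw, xn, z) coordinates and feeds the
  producing-function parameter fit;

* the **relative mesh** places ``points_per_ray`` points at the same
  fractional distances from the peak along six ray segments of fixed
  slopes, clipped at the evaluation-plane edges — corresponding points on
  two surfaces then compare shape independently of where each surface
  sits, and consecutive points bound the bands used by the gradient
  similarity score.

Dome-type surfaces (peaks toward high water) send rays leftward and
downward, with slope = d(xn)/d(xw) so both deltas are negative; trough-
type surfaces (peak at the low-water corner) send rays rightward with the
negated slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DegenerateSurfaceError, InvalidArgumentError
from .surfaces import (
    DEFAULT_GRID,
    EvaluationGrid,
    PeakLocation,
    QuadraticSurface,
)

__all__ = [
    "DEFAULT_RAY_SLOPES", "DEFAULT_RAY_ANGLES", "DEFAULT_CONTOUR_FRACTIONS",
    "MeshSpec", "MeshPointSet", "local_axis", "relative_mesh", "absolute_mesh",
]

DEFAULT_RAY_SLOPES: tuple[float, ...] = (0.0, 0.05, 0.099, 0.175, 0.32, 0.75)
DEFAULT_RAY_ANGLES: tuple[float, ...] = (0.0, 15.0, -15.0, 30.0, -30.0, 45.0, -45.0)
DEFAULT_CONTOUR_FRACTIONS: tuple[float, ...] = (0.05, 0.15, 0.30, 0.50)


@dataclass(frozen=True)
class MeshSpec:
    """Parameters of a mesh.

    ``ray_slopes`` (relative flavor) are listed for dome-type surfaces and
    are negated for trough-type ones; ``ray_angles`` (degrees about the
    local axis) and ``contour_fractions`` (of the peak-to-ray-end z drop,
    in (0, 1]) configure the absolute flavor.
    """

    flavor: str = "relative"  # relative | absolute
    ray_slopes: tuple[float, ...] = DEFAULT_RAY_SLOPES
    ray_angles: tuple[float, ...] = DEFAULT_RAY_ANGLES
    contour_fractions: tuple[float, ...] = DEFAULT_CONTOUR_FRACTIONS
    points_per_ray: int = 10
    include_peak: bool = False

    def __post_init__(self) -> None:
        if self.flavor not in ("relative", "absolute"):
            raise InvalidArgumentError(f"unknown mesh flavor {self.flavor!r}")
        if self.points_per_ray < 2:
            raise InvalidArgumentError("points_per_ray must be >= 2")
        if self.flavor == "absolute":
            if not self.contour_fractions:
                raise InvalidArgumentError("contour_fractions must be nonempty")
            if any(not (0.0 < f <= 1.0) for f in self.contour_fractions):
                raise InvalidArgumentError("contour fractions must be in (0, 1]")


@dataclass
class MeshPointSet:
    """Ordered (ray, position) lattice of (xw, xn, z) samples on one surface.

    ``points`` columns: ray_index, position_index, xw, xn, z, flag
    (empty string, 'collapsed' for zero-length rays, 'missing' for
    contour/ray pairs without an intersection). ``zmin``/``zmax`` record
    the surface's range over the evaluation grid (its amplitude), used by
    the gradient similarity score.
    """

    surface_label: str
    flavor: str
    points: pd.DataFrame
    peak: PeakLocation
    spec: MeshSpec
    local_axis: np.ndarray | None = None
    zmin: float = np.nan
    zmax: float = np.nan

    @property
    def amplitude(self) -> float:
        return abs(self.zmax - self.zmin)

    def valid_points(self) -> pd.DataFrame:
        return self.points[self.points["flag"] == ""]


def local_axis(surface: QuadraticSurface) -> np.ndarray:
    """Local axis of a quadratic surface as a unit 2-vector.

    For an elliptic quadratic part (4*b3*b4 > b5^2) this is the Hessian
    eigenvector with the smaller-magnitude eigenvalue — the slow-curvature
    (apparent major-axis) direction. For a hyperbolic part it is the
    bisector of the two asymptote directions of the trough/saddle. The
    sign is chosen so the water component is >= 0 (nitrogen >= 0 breaking
    the tie for a vertical axis).
    """
    b3, b4, b5 = surface.beta3, surface.beta4, surface.beta5
    scale = max(abs(b3), abs(b4), abs(b5))
    if scale == 0.0:
        raise DegenerateSurfaceError(f"{surface.label}: quadratic part identically zero")
    disc = 4.0 * b3 * b4 - b5 * b5
    if abs(disc) <= 1e-12 * scale * scale:
        raise DegenerateSurfaceError(f"{surface.label}: parabolic quadratic part")
    if disc > 0:
        evals, evecs = np.linalg.eigh(surface.hessian)
        axis = evecs[:, int(np.argmin(np.abs(evals)))]
    else:
        # asymptote directions: Q(1, t) = 0 -> b4 t^2 + b5 t + b3 = 0
        if abs(b4) > 1e-14 * scale:
            t1, t2 = np.roots([b4, b5, b3])
            d1 = np.array([1.0, float(np.real(t1))])
            d2 = np.array([1.0, float(np.real(t2))])
        else:
            # one asymptote is the nitrogen axis (xw = 0)
            d1 = np.array([1.0, -b3 / b5])
            d2 = np.array([0.0, 1.0])
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        for d in (d1, d2):
            if d[0] < 0 or (d[0] == 0 and d[1] < 0):
                d *= -1.0
        axis = d1 + d2
    axis = axis / np.linalg.norm(axis)
    if axis[0] < 0 or (abs(axis[0]) < 1e-14 and axis[1] < 0):
        axis = -axis
    return axis


def _clip_length(peak: PeakLocation, direction: np.ndarray, grid: EvaluationGrid) -> float:
    """Length of the segment from the peak along ``direction`` to the first
    evaluation-plane edge (0 when the peak sits on an outgoing edge)."""
    (wlo, whi), (nlo, nhi) = grid.water_interval, grid.nitrogen_interval
    t = np.inf
    for coord, d, lo, hi in (
        (peak.xw, direction[0], wlo, whi),
        (peak.xn, direction[1], nlo, nhi),
    ):
        if d > 1e-15:
            t = min(t, (hi - coord) / d)
        elif d < -1e-15:
            t = min(t, (lo - coord) / d)
    if not np.isfinite(t):
        raise InvalidArgumentError("ray direction is the zero vector")
    return max(t, 0.0)


def relative_mesh(
    evaluator,
    peak: PeakLocation,
    spec: MeshSpec = MeshSpec(),
    grid: EvaluationGrid = DEFAULT_GRID,
    trough: bool = False,
    surface_label: str = "",
) -> MeshPointSet:
    """Build the relative mesh: ``points_per_ray`` points per ray at fractions
    k/points_per_ray of the clipped segment length.

    ``evaluator`` is any callable z(xw, xn). Dome-type rays run along
    (-1, -slope); trough-type (``trough=True``) along (+1, -slope), i.e.
    with negated slopes. Rays of zero clipped length collapse onto the
    peak and every point on them is flagged 'collapsed'.
    """
    if not grid.contains(peak.xw, peak.xn):
        raise InvalidArgumentError("peak lies outside the evaluation grid")
    zgrid = np.asarray(evaluator(
        *np.meshgrid(grid.water_axis(), grid.nitrogen_axis(), indexing="ij")
    ), dtype=float)
    ux = 1.0 if trough else -1.0
    rows = []
    for ray_idx, slope in enumerate(spec.ray_slopes):
        direction = np.array([ux, -slope])
        direction = direction / np.linalg.norm(direction)
        t_max = _clip_length(peak, direction, grid)
        collapsed = t_max <= 0.0
        for k in range(1, spec.points_per_ray + 1):
            frac = k / spec.points_per_ray
            xw = peak.xw + frac * t_max * direction[0]
            xn = peak.xn + frac * t_max * direction[1]
            rows.append((ray_idx, k, xw, xn, float(evaluator(xw, xn)),
                         "collapsed" if collapsed else ""))
    points = pd.DataFrame(
        rows, columns=["ray_index", "position_index", "xw", "xn", "z", "flag"]
    )
    return MeshPointSet(
        surface_label=surface_label, flavor="relative", points=points, peak=peak,
        spec=replace(spec, flavor="relative"),
        zmin=float(zgrid.min()), zmax=float(zgrid.max()),
    )


def _bisect_contour(evaluator, peak, direction, t_end, z_target, tol=1e-6):
    """First t in (0, t_end] where z crosses z_target, or None."""
    n_probe = 256
    ts = np.linspace(0.0, t_end, n_probe + 1)
    zs = np.array([
        float(evaluator(peak.xw + t * direction[0], peak.xn + t * direction[1]))
        for t in ts
    ])
    g = zs - z_target
    crossing = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) <= 0)
    crossing = crossing[np.abs(g[crossing]) + np.abs(g[crossing + 1]) > 0]
    if crossing.size == 0:
        return None
    lo, hi = ts[crossing[0]], ts[crossing[0] + 1]
    glo = g[crossing[0]]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = float(evaluator(peak.xw + mid * direction[0],
                             peak.xn + mid * direction[1])) - z_target
        if abs(gm) < tol:
            return mid
        if np.sign(gm) == np.sign(glo):
            lo, glo = mid, gm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def absolute_mesh(
    evaluator,
    peak: PeakLocation,
    axis: np.ndarray,
    spec: MeshSpec = MeshSpec(flavor="absolute"),
    grid: EvaluationGrid = DEFAULT_GRID,
    surface_label: str = "",
) -> MeshPointSet:
    """Build the absolute mesh: contour x ray intersections about the peak.

    Rays fan at ``spec.ray_angles`` about the local axis; the base
    direction is whichever sign of the axis gives the longer in-plane
    segment from the peak. Along each ray, for each contour fraction f,
    the point is where z first crosses ``zpeak - f * (zpeak - z_ray_end)``
    (bisection to |dz| < 1e-6). Missing intersections are flagged; the
    peak itself is appended (ray_index -1) iff ``spec.include_peak``.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if _clip_length(peak, -axis, grid) >= _clip_length(peak, axis, grid):
        base = -axis
    else:
        base = axis
    zgrid = np.asarray(evaluator(
        *np.meshgrid(grid.water_axis(), grid.nitrogen_axis(), indexing="ij")
    ), dtype=float)
    zpeak = float(evaluator(peak.xw, peak.xn))
    rows = []
    for ray_idx, angle in enumerate(spec.ray_angles):
        rad = np.deg2rad(angle)
        rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        direction = rot @ base
        t_end = _clip_length(peak, direction, grid)
        if t_end <= 0.0:
            for pos_idx, frac in enumerate(spec.contour_fractions, start=1):
                rows.append((ray_idx, pos_idx, peak.xw, peak.xn, zpeak, "collapsed"))
            continue
        z_end = float(evaluator(peak.xw + t_end * direction[0],
                                peak.xn + t_end * direction[1]))
        for pos_idx, frac in enumerate(spec.contour_fractions, start=1):
            z_target = zpeak - frac * (zpeak - z_end)
            t = _bisect_contour(evaluator, peak, direction, t_end, z_target)
            if t is None:
                rows.append((ray_idx, pos_idx, np.nan, np.nan, np.nan, "missing"))
            else:
                xw = peak.xw + t * direction[0]
                xn = peak.xn + t * direction[1]
                rows.append((ray_idx, pos_idx, xw, xn, float(evaluator(xw, xn)), ""))
    if spec.include_peak:
        rows.append((-1, 0, peak.xw, peak.xn, zpeak, ""))
    points = pd.DataFrame(
        rows, columns=["ray_index", "position_index", "xw", "xn", "z", "flag"]
    )
    return MeshPointSet(
        surface_label=surface_label, flavor="absolute", points=points, peak=peak,
        spec=replace(spec, flavor="absolute"), local_axis=base,
        zmin=float(zgrid.min()), zmax=float(zgrid.max()),
    )
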