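"""Response-surface models, grid evaluation, peak location and shape classes.

Two surface models describe how maize growth (``z``, difference in plant
height, cm) responds to recentred water (``xw``) and nitrogen (``xn``)
stress covariates:

* a quadratic regression surface
  ``z = b1*xw + b2*xn + b3*xw^2 + b4*xn^2 + b5*xw*xn + ell``
  — the smoothed, per-line/per-allele fit used in QTL mapping, where
  ``ell`` lumps together all constant terms (grand mean, line effect,
  residual intercept); and

* a mechanistic *producing function*
  ``z = c*(a*xw^2 + b*xn^2) + d*xw + e*xn``
  — an elliptical paraboloid plus a tilted plane, with no constant term.
  ``c < 0`` gives a convex-upward (domed) paraboloid, ``c > 0`` a
  concave-upward trough.

Surfaces are evaluated on a rectangular grid over the recentred design
region (water ``[-42, 42]``, nitrogen ``[-7.5, 7.5]``, step 0.5 by
default), and peaks are located by exhaustive grid search: reported peak
coordinates are grid-quantized, which is what makes them comparable
across analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "QuadraticSurface",
    "ProducingFunctionParams",
    "EvaluationGrid",
    "PeakLocation",
    "ShapeCategory",
    "DEFAULT_GRID",
    "evaluate_quadratic",
    "evaluate_producing",
    "surface_grid",
    "find_peak",
    "classify_shape",
    "sign_pattern",
    "dominant_curvature_sign",
]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise InvalidArgumentError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class QuadraticSurface:
    """Coefficients of one line's/allele's smoothed quadratic response surface.

    ``beta1``/``beta2`` are the linear water/nitrogen terms (cm per unit),
    ``beta3``/``beta4`` the quadratic terms, ``beta5`` the water x nitrogen
    interaction, and ``ell`` the lumped constant (cm).
    """

    label: str
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    ell: float

    def __post_init__(self) -> None:
        _require_finite(
            f"QuadraticSurface({self.label})",
            self.beta1, self.beta2, self.beta3, self.beta4, self.beta5, self.ell,
        )

    def __call__(self, xw, xn):
        return evaluate_quadratic(self, xw, xn)

    @property
    def hessian(self) -> np.ndarray:
        """Hessian of the quadratic part, [[2*b3, b5], [b5, 2*b4]]."""
        return np.array([[2.0 * self.beta3, self.beta5],
                         [self.beta5, 2.0 * self.beta4]])


@dataclass(frozen=True)
class ProducingFunctionParams:
    """The five producing-function parameters.

    ``a`` and ``b`` weight water and nitrogen in the elliptical paraboloid,
    ``c`` scales and orients it (c < 0: convex upward / single maximum),
    ``d`` and ``e`` tilt the planar component along water and nitrogen.
    Only the products ``c*a`` and ``c*b`` are identifiable from data; ``c``
    is conventionally preset to -1 (domed) or +1 (trough).
    """

    label: str
    a: float
    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        _require_finite(
            f"ProducingFunctionParams({self.label})",
            self.a, self.b, self.c, self.d, self.e,
        )

    def __call__(self, xw, xn):
        return evaluate_producing(self, xw, xn)

    def stationary_point(self) -> tuple[float, float] | None:
        """Unconstrained stationary point of z, or None if the paraboloid
        degenerates along either axis (c*a == 0 or c*b == 0)."""
        ca, cb = self.c * self.a, self.c * self.b
        if ca == 0.0 or cb == 0.0:
            return None
        return (-self.d / (2.0 * ca), -self.e / (2.0 * cb))


@dataclass(frozen=True)
class EvaluationGrid:
    """Rectangular evaluation lattice over recentred (xw, xn).

    Defaults cover the design region: water [-42, 42], nitrogen
    [-7.5, 7.5], step 0.5 (169 x 31 = 5239 nodes). Interval endpoints
    must be integer multiples of the step from the lower bound.
    """

    water_interval: tuple[float, float] = (-42.0, 42.0)
    nitrogen_interval: tuple[float, float] = (-7.5, 7.5)
    step: float = 0.5

    def __post_init__(self) -> None:
        if not (self.step > 0 and math.isfinite(self.step)):
            raise InvalidArgumentError(f"step must be positive, got {self.step}")
        for name, (lo, hi) in (
            ("water_interval", self.water_interval),
            ("nitrogen_interval", self.nitrogen_interval),
        ):
            _require_finite(name, lo, hi)
            if hi <= lo:
                raise InvalidArgumentError(f"{name}: degenerate interval [{lo}, {hi}]")
            n = (hi - lo) / self.step
            if abs(n - round(n)) > 1e-9:
                raise InvalidArgumentError(
                    f"{name}: endpoints not an integer number of steps apart"
                )

    @property
    def n_water(self) -> int:
        lo, hi = self.water_interval
        return int(round((hi - lo) / self.step)) + 1

    @property
    def n_nitrogen(self) -> int:
        lo, hi = self.nitrogen_interval
        return int(round((hi - lo) / self.step)) + 1

    def water_axis(self) -> np.ndarray:
        lo, hi = self.water_interval
        return np.linspace(lo, hi, self.n_water)

    def nitrogen_axis(self) -> np.ndarray:
        lo, hi = self.nitrogen_interval
        return np.linspace(lo, hi, self.n_nitrogen)

    def contains(self, xw: float, xn: float, margin: float = 0.0) -> bool:
        """True if (xw, xn) lies in the plane inflated by ``margin`` (fraction
        of each half-width) about the grid center."""
        (wlo, whi), (nlo, nhi) = self.water_interval, self.nitrogen_interval
        wpad = 0.5 * (whi - wlo) * margin
        npad = 0.5 * (nhi - nlo) * margin
        return (wlo - wpad <= xw <= whi + wpad) and (nlo - npad <= xn <= nhi + npad)


DEFAULT_GRID = EvaluationGrid()


@dataclass(frozen=True)
class PeakLocation:
    """Grid node of maximal z. ``on_boundary`` marks edge/corner maxima."""

    xw: float
    xn: float
    zmax: float
    on_boundary: bool


@dataclass(frozen=True)
class ShapeCategory:
    """One of the four surface shape classes; ``ambiguous`` marks peaks within
    one grid step of a classification threshold."""

    category: str  # domed | hybrid | shoulder | trough
    ambiguous: bool = False


def evaluate_quadratic(surface: QuadraticSurface, xw, xn):
    """Evaluate the quadratic surface at (xw, xn); accepts scalars or arrays."""
    xw = np.asarray(xw, dtype=float)
    xn = np.asarray(xn, dtype=float)
    if not (np.all(np.isfinite(xw)) and np.all(np.isfinite(xn))):
        raise InvalidArgumentError("evaluate_quadratic: non-finite coordinates")
    z = (
        surface.beta1 * xw
        + surface.beta2 * xn
        + surface.beta3 * xw**2
        + surface.beta4 * xn**2
        + surface.beta5 * xw * xn
        + surface.ell
    )
    return float(z) if z.ndim == 0 else z


def evaluate_producing(params: ProducingFunctionParams, xw, xn):
    """Evaluate the producing function at (xw, xn); exactly 0 at the origin."""
    xw = np.asarray(xw, dtype=float)
    xn = np.asarray(xn, dtype=float)
    if not (np.all(np.isfinite(xw)) and np.all(np.isfinite(xn))):
        raise InvalidArgumentError("evaluate_producing: non-finite coordinates")
    z = params.c * (params.a * xw**2 + params.b * xn**2) + params.d * xw + params.e * xn
    return float(z) if z.ndim == 0 else z


def surface_grid(model, grid: EvaluationGrid = DEFAULT_GRID) -> np.ndarray:
    """Evaluate ``model`` on every grid node.

    Returns an (n_water, n_nitrogen) matrix with water ascending along rows
    and nitrogen ascending along columns. ``model`` may be a
    QuadraticSurface, ProducingFunctionParams, or any callable z(xw, xn).
    """
    xw, xn = np.meshgrid(grid.water_axis(), grid.nitrogen_axis(), indexing="ij")
    return np.asarray(model(xw, xn), dtype=float)


def find_peak(zvalues: np.ndarray, grid: EvaluationGrid = DEFAULT_GRID) -> PeakLocation:
    """Locate the grid node with maximal z by exhaustive search.

    Ties are broken toward smaller xw, then smaller xn (the first maximal
    node in row-major order). ``on_boundary`` is True iff the argmax lies
    on an interval endpoint in either axis.
    """
    z = np.asarray(zvalues, dtype=float)
    if z.size == 0:
        raise InvalidArgumentError("find_peak: empty matrix")
    if z.shape != (grid.n_water, grid.n_nitrogen):
        raise InvalidArgumentError(
            f"find_peak: matrix shape {z.shape} does not match grid "
            f"({grid.n_water}, {grid.n_nitrogen})"
        )
    i, j = np.unravel_index(int(np.argmax(z)), z.shape)
    xw = grid.water_axis()[i]
    xn = grid.nitrogen_axis()[j]
    boundary = i in (0, grid.n_water - 1) or j in (0, grid.n_nitrogen - 1)
    return PeakLocation(xw=float(xw), xn=float(xn), zmax=float(z[i, j]),
                        on_boundary=bool(boundary))


def dominant_curvature_sign(surface: QuadraticSurface,
                            grid: EvaluationGrid = DEFAULT_GRID) -> int:
    """Sign of the quadratic part averaged over the grid.

    Plays the role of the producing function's preset ``c`` for quadratic
    surfaces: -1 for surfaces whose dominant curvature is convex upward
    (domed), +1 for concave upward (trough). The water axis spans a much
    wider range than nitrogen, so the mean is dominated by the water
    curvature unless that term is negligible.
    """
    w2 = float(np.mean(grid.water_axis() ** 2))
    n2 = float(np.mean(grid.nitrogen_axis() ** 2))
    # cross term averages to zero on the symmetric grid
    mean_q = surface.beta3 * w2 + surface.beta4 * n2
    return 1 if mean_q > 0 else -1


def classify_shape(
    peak: PeakLocation,
    curvature_sign: float,
    *,
    shoulder_min_xw: float = 36.0,
    domed_min_xw: float = 27.0,
    step: float = 0.5,
) -> ShapeCategory:
    """Assign one of the four shape categories from peak position and curvature.

    Rule: trough if the curvature sign is positive (concave upward); else
    shoulder if the peak's xw >= ``shoulder_min_xw``; else domed if
    xw > ``domed_min_xw``; else hybrid. The thresholds are conventions —
    category membership genuinely depends on the classification criteria —
    so they are exposed, and ``ambiguous`` is set when xw lies within one
    grid step of either threshold.
    """
    if curvature_sign > 0:
        return ShapeCategory("trough", ambiguous=False)
    ambiguous = (
        abs(peak.xw - shoulder_min_xw) <= step or abs(peak.xw - domed_min_xw) <= step
    )
    if peak.xw >= shoulder_min_xw:
        return ShapeCategory("shoulder", ambiguous=ambiguous)
    if peak.xw > domed_min_xw:
        return ShapeCategory("domed", ambiguous=ambiguous)
    return ShapeCategory("hybrid", ambiguous=ambiguous)


def sign_pattern(params: ProducingFunctionParams) -> tuple[str, str, str, str]:
    """Ordered signs of (a, b, d, e); '0' only for exactly-zero parameters."""

    def sgn(v: float) -> str:
        if v == 0.0:
            return "0"
        return "+" if v > 0 else "-"

    return (sgn(params.a), sgn(params.b), sgn(params.d), sgn(params.e))
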