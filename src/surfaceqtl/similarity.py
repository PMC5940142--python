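"""Mesh-based similarity scores between pairs of response surfaces.

Given an *experimental* surface e and a *simulated* (model) surface s,
each discretized by a relative mesh anchored at its own peak with the
same ray structure, three scores are computed at corresponding mesh
points:

* ``rho`` — signed Euclidean displacement in (xw, xn, z) space,
  sign(z_s - z_e) * ||p_s - p_e||: where the model surface sits relative
  to the experimental one;
* ``theta`` — the signed angle (degrees, counter-clockwise positive) at
  the evaluation-plane origin between the projected positions of the two
  corresponding points: relative in-plane rotation;
* ``delta_zr`` — per ray band (consecutive point pair), the difference of
  amplitude-normalized discrete z-gradients, g_s - g_e with
  g = dz / (planar distance * |zmax - zmin|): differences in how steeply
  the surfaces bend, independent of overall scale. Negative values mean
  the simulation descends more steeply.

``compare_all`` assembles the all-pairs score matrices with columns
ordered as concentric rings around the peaks (all rays at position 1,
then position 2, ...), each experimental surface compared first to its
model sibling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .mesh import MeshPointSet, MeshSpec, relative_mesh
from .surfaces import (
    DEFAULT_GRID,
    EvaluationGrid,
    ProducingFunctionParams,
    find_peak,
    surface_grid,
)

__all__ = [
    "SimilarityScores", "ComparisonResult",
    "rho_score", "theta_score", "delta_zr_score", "compare_all",
    "admit_simulated_surface",
]

logger = logging.getLogger(__name__)


def _check_compatible(exp: MeshPointSet, sim: MeshPointSet) -> None:
    for mesh in (exp, sim):
        if mesh.flavor != "relative":
            raise InvalidArgumentError("similarity scores are defined on relative meshes")
    if (exp.spec.ray_slopes != sim.spec.ray_slopes
            or exp.spec.points_per_ray != sim.spec.points_per_ray):
        raise InvalidArgumentError("meshes have mismatched ray specs")
    if len(exp.points) != len(sim.points):
        raise InvalidArgumentError("meshes have different point counts")


@dataclass
class SimilarityScores:
    """Scores for one (experimental, simulated) surface pair."""

    pair: tuple[str, str]
    rho: np.ndarray          # one per mesh point
    theta: np.ndarray        # degrees, one per mesh point (NaN where undefined)
    delta_zr: np.ndarray     # one per (ray, band)
    n_rays: int
    points_per_ray: int


def rho_score(exp: MeshPointSet, sim: MeshPointSet) -> np.ndarray:
    """Signed 3-D displacement at each corresponding mesh point."""
    _check_compatible(exp, sim)
    pe = exp.points[["xw", "xn", "z"]].to_numpy(float)
    ps = sim.points[["xw", "xn", "z"]].to_numpy(float)
    dist = np.linalg.norm(ps - pe, axis=1)
    sign = np.sign(ps[:, 2] - pe[:, 2])
    sign[sign == 0] = 1.0
    out = sign * dist
    out[dist == 0] = 0.0
    return out


def theta_score(exp: MeshPointSet, sim: MeshPointSet) -> np.ndarray:
    """Signed origin-subtended rotation (degrees) between projected points.

    Points whose projection coincides with the evaluation-plane origin have
    no defined angle and yield NaN.
    """
    _check_compatible(exp, sim)
    pe = exp.points[["xw", "xn"]].to_numpy(float)
    ps = sim.points[["xw", "xn"]].to_numpy(float)
    cross = pe[:, 0] * ps[:, 1] - pe[:, 1] * ps[:, 0]
    dot = np.einsum("ij,ij->i", pe, ps)
    theta = np.degrees(np.arctan2(cross, dot))
    undefined = (np.linalg.norm(pe, axis=1) == 0) | (np.linalg.norm(ps, axis=1) == 0)
    theta[undefined] = np.nan
    return theta


def _ray_gradients(mesh: MeshPointSet) -> np.ndarray:
    """Amplitude-normalized discrete gradients per (ray, band)."""
    amp = mesh.amplitude
    grads = []
    for _, ray in mesh.points.groupby("ray_index", sort=True):
        ray = ray.sort_values("position_index")
        xy = ray[["xw", "xn"]].to_numpy(float)
        z = ray["z"].to_numpy(float)
        planar = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        dz = np.diff(z)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = dz / (planar * amp)
        g[planar == 0] = np.nan  # collapsed band: undefined
        grads.append(g)
    return np.concatenate(grads)


def delta_zr_score(exp: MeshPointSet, sim: MeshPointSet) -> np.ndarray:
    """Difference of relative discrete gradients, simulation minus experiment,
    per ray band. Negative: the simulation descends more steeply."""
    _check_compatible(exp, sim)
    return _ray_gradients(sim) - _ray_gradients(exp)


def score_pair(exp: MeshPointSet, sim: MeshPointSet) -> SimilarityScores:
    return SimilarityScores(
        pair=(exp.surface_label, sim.surface_label),
        rho=rho_score(exp, sim),
        theta=theta_score(exp, sim),
        delta_zr=delta_zr_score(exp, sim),
        n_rays=len(exp.spec.ray_slopes),
        points_per_ray=exp.spec.points_per_ray,
    )


def admit_simulated_surface(
    params: ProducingFunctionParams,
    spec: MeshSpec = MeshSpec(),
    grid: EvaluationGrid = DEFAULT_GRID,
    margin: float = 0.10,
) -> tuple[MeshPointSet | None, str]:
    """Build a model surface's relative mesh, or explain why it is excluded.

    A simulated surface cannot be compared when it is displaced too far in
    the evaluation plane: concretely, when its grid peak sits on a plane
    edge that blocks the ray fan (any ray of its relative mesh collapses
    to zero length), or when a definite-maximum paraboloid has its
    unconstrained peak outside the plane inflated by ``margin``. The ray
    direction follows the preset orientation: trough-type surfaces
    (c > 0) send rays rightward, all others leftward-downward.
    Returns (mesh, "") when admitted, (None, reason) when excluded.
    """
    trough = params.c > 0
    ca, cb = params.c * params.a, params.c * params.b
    if ca < 0 and cb < 0:
        stat = params.stationary_point()
        if stat is not None and not grid.contains(stat[0], stat[1], margin=margin):
            return None, (
                f"unconstrained peak ({stat[0]:.1f}, {stat[1]:.1f}) outside the "
                f"evaluation plane inflated by {margin:.0%}"
            )
    peak = find_peak(surface_grid(params, grid), grid)
    mesh = relative_mesh(params, peak, spec=spec, grid=grid, trough=trough,
                         surface_label=params.label)
    n_collapsed = int((mesh.points["flag"] == "collapsed").sum()) // spec.points_per_ray
    if n_collapsed:
        return None, (
            f"displaced too far in the evaluation plane: peak "
            f"({peak.xw:.1f}, {peak.xn:.1f}) lies on an edge blocking "
            f"{n_collapsed} of {len(spec.ray_slopes)} rays"
        )
    return mesh, ""


def _ring_columns(n_rays: int, points_per_ray: int) -> list[str]:
    return [f"p{k}_r{r}" for k in range(1, points_per_ray + 1) for r in range(n_rays)]


def _ring_order(values: np.ndarray, n_rays: int, points_per_ray: int) -> np.ndarray:
    """Reorder a ray-major vector (ray 0 positions 1..n, ray 1 ...) into
    concentric-ring order (all rays at position 1, then position 2, ...)."""
    return values.reshape(n_rays, points_per_ray).T.reshape(-1)


@dataclass
class ComparisonResult:
    """All-pairs similarity matrices with ring-ordered columns."""

    scores: list[SimilarityScores]
    rho: pd.DataFrame
    theta: pd.DataFrame
    delta_zr: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)


def compare_all(
    experimental: dict[str, MeshPointSet],
    simulated: dict[str, MeshPointSet],
    excluded: dict[str, str] | None = None,
) -> ComparisonResult:
    """Score every experimental mesh against every admitted simulated mesh.

    Rows are (e, s) pairs, each experimental surface's same-label sibling
    first; ``excluded`` carries the already-logged reasons for simulated
    surfaces that were dropped before meshing.
    """
    excluded = dict(excluded or {})
    scores: list[SimilarityScores] = []
    for e_label, e_mesh in experimental.items():
        sim_order = sorted(simulated, key=lambda s: (s != e_label,))
        for s_label in sim_order:
            scores.append(score_pair(e_mesh, simulated[s_label]))
    if not scores:
        return ComparisonResult(scores=[], rho=pd.DataFrame(), theta=pd.DataFrame(),
                                delta_zr=pd.DataFrame(), excluded=excluded)
    n_rays = scores[0].n_rays
    ppr = scores[0].points_per_ray
    idx = [f"e:{e}|s:{s}" for (e, s) in (sc.pair for sc in scores)]
    rho = pd.DataFrame(
        [_ring_order(sc.rho, n_rays, ppr) for sc in scores],
        index=idx, columns=_ring_columns(n_rays, ppr),
    )
    theta = pd.DataFrame(
        [_ring_order(sc.theta, n_rays, ppr) for sc in scores],
        index=idx, columns=_ring_columns(n_rays, ppr),
    )
    band_cols = [f"b{k}_r{r}" for k in range(1, ppr) for r in range(n_rays)]
    delta = pd.DataFrame(
        [_ring_order(sc.delta_zr, n_rays, ppr - 1) for sc in scores],
        index=idx, columns=band_cols,
    )
    return ComparisonResult(scores=scores, rho=rho, theta=theta, delta_zr=delta,
                            excluded=excluded)


def build_relative_meshes(
    surfaces: dict[str, object],
    trough_flags: dict[str, bool],
    spec: MeshSpec = MeshSpec(),
    grid: EvaluationGrid = DEFAULT_GRID,
) -> dict[str, MeshPointSet]:
    """Relative meshes for a set of surfaces, each anchored at its own grid peak."""
    meshes = {}
    for label, model in surfaces.items():
        peak = find_peak(surface_grid(model, grid), grid)
        meshes[label] = relative_mesh(
            model, peak, spec=spec, grid=grid,
            trough=trough_flags.get(label, False), surface_label=label,
        )
    return meshes
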