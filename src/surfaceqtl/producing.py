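"""Least-squares estimation of producing-function parameters over a mesh.

With the paraboloid orientation ``c`` preset (-1 for domed surfaces, +1
for troughs), the producing function

    z = c*(a*xw^2 + b*xn^2) + d*xw + e*xn

is linear in (a, b, d, e): the fit is an ordinary least squares of the
mesh z-values on the four columns (c*xw^2, c*xn^2, xw, xn), with no
intercept. Only the products c*a and c*b are identifiable; the reported
``a`` and ``b`` are the fitted products divided by the preset ``c`` and
are interpretable only jointly with it.

The scalar fit quality ``s`` is the square root of the least-squares
objective at the solution (the residual 2-norm over the mesh points); it
is not normalized by point count. ``residual_norm`` reports the constraint
violation of the solver, which is identically zero for this unconstrained
problem, and is kept separate from ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, RankDeficiencyError
from .mesh import MeshPointSet
from .surfaces import ProducingFunctionParams, sign_pattern

__all__ = ["ProducingFit", "fit_producing", "compare_estimation_variants"]


@dataclass
class ProducingFit:
    """Result of fitting the producing function to one mesh."""

    params: ProducingFunctionParams
    s: float
    residual_norm: float
    n_points: int
    mesh_flavor: str


def fit_producing(mesh: MeshPointSet, c: float, label: str | None = None) -> ProducingFit:
    """Fit (a, b, d, e) at preset ``c`` by least squares over the mesh.

    Flagged (collapsed/missing) mesh points are excluded. Raises
    :class:`RankDeficiencyError` when the remaining points do not span the
    four design columns (e.g. all points collinear).
    """
    if c == 0.0 or not np.isfinite(c):
        raise InvalidArgumentError("preset c must be finite and nonzero")
    pts = mesh.valid_points()
    if len(pts) < 4:
        raise InvalidArgumentError("need at least 4 usable mesh points")
    xw = pts["xw"].to_numpy(float)
    xn = pts["xn"].to_numpy(float)
    z = pts["z"].to_numpy(float)
    X = np.column_stack([c * xw**2, c * xn**2, xw, xn])
    if np.linalg.matrix_rank(X) < 4:
        raise RankDeficiencyError("mesh points do not span the producing-function design")
    coef, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ coef
    a, b, d, e = (float(v) for v in coef)
    params = ProducingFunctionParams(
        label=label or mesh.surface_label or "fit", a=a, b=b, c=float(c), d=d, e=e
    )
    return ProducingFit(
        params=params,
        s=float(np.sqrt(resid @ resid)),
        residual_norm=0.0,
        n_points=len(pts),
        mesh_flavor=mesh.flavor,
    )


def compare_estimation_variants(
    meshes: dict[str, MeshPointSet], c: float, label: str | None = None
) -> pd.DataFrame:
    """Fit the producing function on several mesh variants of one surface.

    ``meshes`` maps a variant name (e.g. 'absolute', 'absolute_no_peak',
    'relative') to the mesh; returns one row per variant with the fitted
    parameters, ``s`` and the sign pattern, for side-by-side reporting.
    """
    rows = []
    for variant, mesh in meshes.items():
        fit = fit_producing(mesh, c, label=label)
        sa, sb, sd, se = sign_pattern(fit.params)
        rows.append({
            "variant": variant, "label": fit.params.label,
            "a": fit.params.a, "b": fit.params.b, "c": fit.params.c,
            "d": fit.params.d, "e": fit.params.e, "s": fit.s,
            "residual_norm": fit.residual_norm, "n_points": fit.n_points,
            "sgn_a": sa, "sgn_b": sb, "sgn_d": sd, "sgn_e": se,
        })
    return pd.DataFrame(rows)
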