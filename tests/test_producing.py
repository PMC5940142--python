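"""Producing-function parameter estimation over meshes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from surfaceqtl.exceptions import InvalidArgumentError, RankDeficiencyError
from surfaceqtl.mesh import MeshPointSet, MeshSpec, relative_mesh
from surfaceqtl.producing import compare_estimation_variants, fit_producing
from surfaceqtl.surfaces import (
    DEFAULT_GRID,
    PeakLocation,
    ProducingFunctionParams,
    evaluate_producing,
    find_peak,
    surface_grid,
)
from surfaceqtl.tables import (
    EXAMPLE_DOMED_PARAMS,
    EXAMPLE_TROUGH_PARAMS,
    EXPERIMENTAL_SURFACES,
)


def _mesh_from_points(xw, xn, z, label="synthetic"):
    n = len(xw)
    points = pd.DataFrame({
        "ray_index": np.zeros(n, dtype=int), "position_index": np.arange(n),
        "xw": xw, "xn": xn, "z": z, "flag": [""] * n,
    })
    return MeshPointSet(surface_label=label, flavor="relative", points=points,
                        peak=PeakLocation(0, 0, 0, False), spec=MeshSpec(),
                        zmin=float(np.min(z)), zmax=float(np.max(z)))


def _random_full_rank_mesh(rng, params):
    xw = rng.uniform(-42, 42, 25)
    xn = rng.uniform(-7.5, 7.5, 25)
    z = evaluate_producing(params, xw, xn)
    return _mesh_from_points(xw, xn, z)


class TestRecovery:
    @pytest.mark.parametrize("params", [EXAMPLE_DOMED_PARAMS, EXAMPLE_TROUGH_PARAMS])
    def test_model_class_surface_recovered_exactly(self, params):
        """For a surface generated by the model itself, the fit recovers the
        identifiable quantities (c*a, c*b, d, e) to 1e-8 with s ~ 0, and
        matches an independent normal-equations oracle."""
        rng = np.random.default_rng(1)
        mesh = _random_full_rank_mesh(rng, params)
        c = -1.0 if params.c < 0 else 1.0
        fit = fit_producing(mesh, c)
        assert c * fit.params.a == pytest.approx(params.c * params.a, abs=1e-8)
        assert c * fit.params.b == pytest.approx(params.c * params.b, abs=1e-8)
        assert fit.params.d == pytest.approx(params.d, abs=1e-8)
        assert fit.params.e == pytest.approx(params.e, abs=1e-8)
        assert fit.s == pytest.approx(0.0, abs=1e-8)
        assert fit.residual_norm == 0.0
        # normal-equations oracle
        pts = mesh.points
        X = np.column_stack([c * pts["xw"]**2, c * pts["xn"]**2,
                             pts["xw"], pts["xn"]])
        beta = np.linalg.solve(X.T @ X, X.T @ pts["z"].to_numpy())
        assert np.allclose([fit.params.a, fit.params.b, fit.params.d, fit.params.e],
                           beta, atol=1e-8)

    def test_recovery_on_grid_anchored_relative_mesh(self):
        """Same exact recovery when the mesh is the standard relative mesh
        built on the surface's own grid peak."""
        params = EXAMPLE_DOMED_PARAMS
        peak = find_peak(surface_grid(params, DEFAULT_GRID), DEFAULT_GRID)
        mesh = relative_mesh(params, peak, grid=DEFAULT_GRID, surface_label="d")
        fit = fit_producing(mesh, -1.0)
        assert -fit.params.a == pytest.approx(params.c * params.a, abs=1e-10)
        assert fit.params.d == pytest.approx(params.d, abs=1e-10)
        assert fit.s == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_heights_give_zero_parameters(self):
        rng = np.random.default_rng(2)
        xw = rng.uniform(-42, 42, 12)
        xn = rng.uniform(-7.5, 7.5, 12)
        fit = fit_producing(_mesh_from_points(xw, xn, np.zeros(12)), c=-1.0)
        assert fit.params.a == fit.params.b == fit.params.d == fit.params.e == 0.0
        assert fit.s == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_recovery_property_random_params_and_meshes(self, seed):
        rng = np.random.default_rng(seed)
        c = -1.0 if rng.random() < 0.5 else 1.0
        truth = ProducingFunctionParams(
            "t", a=rng.uniform(-1, 1), b=rng.uniform(-1, 1), c=c,
            d=rng.uniform(-3, 3), e=rng.uniform(-3, 3),
        )
        mesh = _random_full_rank_mesh(rng, truth)
        fit = fit_producing(mesh, c)
        z_hat = evaluate_producing(fit.params, mesh.points["xw"].to_numpy(),
                                   mesh.points["xn"].to_numpy())
        assert np.allclose(z_hat, mesh.points["z"], atol=1e-7)
        assert fit.s < 1e-7

    def test_s_invariant_to_point_order(self):
        rng = np.random.default_rng(3)
        xw = rng.uniform(-42, 42, 30)
        xn = rng.uniform(-7.5, 7.5, 30)
        z = evaluate_producing(EXAMPLE_DOMED_PARAMS, xw, xn) + rng.normal(0, 1, 30)
        m1 = _mesh_from_points(xw, xn, z)
        perm = rng.permutation(30)
        m2 = _mesh_from_points(xw[perm], xn[perm], z[perm])
        assert fit_producing(m1, -1.0).s == pytest.approx(
            fit_producing(m2, -1.0).s, rel=1e-12)

    def test_c_flip_leaves_predictions_unchanged(self):
        """Only c*a and c*b are identifiable: flipping c flips (a, b) and
        leaves the predicted surface invariant."""
        rng = np.random.default_rng(4)
        mesh = _random_full_rank_mesh(rng, EXAMPLE_DOMED_PARAMS)
        f_minus = fit_producing(mesh, -1.0)
        f_plus = fit_producing(mesh, +1.0)
        assert f_plus.params.a == pytest.approx(-f_minus.params.a, abs=1e-10)
        assert f_plus.params.b == pytest.approx(-f_minus.params.b, abs=1e-10)
        xw, xn = rng.uniform(-42, 42, 5), rng.uniform(-7.5, 7.5, 5)
        assert np.allclose(evaluate_producing(f_plus.params, xw, xn),
                           evaluate_producing(f_minus.params, xw, xn))


class TestErrors:
    def test_collinear_mesh_rank_deficient(self):
        xw = np.linspace(-10, 10, 8)
        xn = np.zeros(8)  # xn and xn^2 columns vanish
        with pytest.raises(RankDeficiencyError):
            fit_producing(_mesh_from_points(xw, xn, xw), c=-1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_producing(_mesh_from_points(np.ones(3), np.ones(3), np.ones(3)), -1.0)

    def test_zero_c_rejected(self):
        rng = np.random.default_rng(5)
        mesh = _random_full_rank_mesh(rng, EXAMPLE_DOMED_PARAMS)
        with pytest.raises(InvalidArgumentError):
            fit_producing(mesh, 0.0)


class TestVariants:
    def test_model_class_surface_identical_across_variants(self):
        rng = np.random.default_rng(6)
        meshes = {
            "m1": _random_full_rank_mesh(rng, EXAMPLE_DOMED_PARAMS),
            "m2": _random_full_rank_mesh(rng, EXAMPLE_DOMED_PARAMS),
        }
        table = compare_estimation_variants(meshes, c=-1.0)
        assert np.allclose(table["s"], 0.0, atol=1e-8)
        assert table["a"].nunique() == 1 or np.allclose(np.diff(table["a"]), 0,
                                                        atol=1e-8)

    def test_hyperbolic_misspecification_detected(self):
        """Adding a hyperbolic twist puts the surface outside the model
        class: s > 0 on any mesh."""
        rng = np.random.default_rng(7)
        xw = rng.uniform(-42, 42, 40)
        xn = rng.uniform(-7.5, 7.5, 40)
        z = evaluate_producing(EXAMPLE_DOMED_PARAMS, xw, xn) + 0.01 * xw * xn
        fit = fit_producing(_mesh_from_points(xw, xn, z), c=-1.0)
        assert fit.s > 0.1

    def test_published_surface_fits_with_and_without_peak(self, grid):
        from surfaceqtl.mesh import absolute_mesh, local_axis

        surf = EXPERIMENTAL_SURFACES["B73"]
        peak = find_peak(surface_grid(surf, grid), grid)
        axis = local_axis(surf)
        meshes = {
            "with_peak": absolute_mesh(surf, peak, axis, grid=grid,
                                       spec=MeshSpec(flavor="absolute",
                                                     include_peak=True)),
            "without_peak": absolute_mesh(surf, peak, axis, grid=grid,
                                          spec=MeshSpec(flavor="absolute")),
        }
        table = compare_estimation_variants(meshes, c=-1.0, label="B73")
        assert len(table) == 2
        assert np.isfinite(table["s"]).all()
        assert (table["s"] > 0).all()
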