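"""Local axes and absolute/relative mesh construction."""

import numpy as np
import pytest

from surfaceqtl.exceptions import DegenerateSurfaceError, InvalidArgumentError
from surfaceqtl.mesh import (
    DEFAULT_RAY_SLOPES,
    MeshSpec,
    absolute_mesh,
    local_axis,
    relative_mesh,
)
from surfaceqtl.surfaces import (
    DEFAULT_GRID,
    PeakLocation,
    QuadraticSurface,
    find_peak,
    surface_grid,
)
from surfaceqtl.tables import EXPERIMENTAL_SURFACES

ORIGIN_PEAK = PeakLocation(0.0, 0.0, 0.0, False)


def radial_bowl(xw, xn):
    return -(np.asarray(xw, float) ** 2 + np.asarray(xn, float) ** 2)


class TestLocalAxis:
    def test_axis_aligned_ellipse(self):
        s = QuadraticSurface("e", 0, 0, beta3=-1.0, beta4=-4.0, beta5=0.0, ell=0)
        assert np.allclose(local_axis(s), [1.0, 0.0])

    def test_saddle_bisector(self):
        s = QuadraticSurface("h", 0, 0, beta3=0.0, beta4=0.0, beta5=1.0, ell=0)
        assert np.allclose(local_axis(s), [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_published_domed_surface_matches_eigen_oracle(self):
        s = EXPERIMENTAL_SURFACES["B73"]
        axis = local_axis(s)
        H = np.array([[2 * s.beta3, s.beta5], [s.beta5, 2 * s.beta4]])
        w, v = np.linalg.eigh(H)
        oracle = v[:, np.argmin(np.abs(w))]
        cos = abs(axis @ oracle)
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_degenerate_quadratic_part_rejected(self):
        flat = QuadraticSurface("f", 1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(DegenerateSurfaceError):
            local_axis(flat)
        parabolic = QuadraticSurface("p", 0, 0, beta3=-1.0, beta4=-1.0,
                                     beta5=2.0, ell=0)
        with pytest.raises(DegenerateSurfaceError):
            local_axis(parabolic)


class TestRelativeMesh:
    def test_default_mesh_has_sixty_points_and_nine_bands(self):
        mesh = relative_mesh(radial_bowl, ORIGIN_PEAK)
        assert len(mesh.points) == 60
        per_ray = mesh.points.groupby("ray_index").size()
        assert (per_ray == 10).all() and len(per_ray) == 6
        # bands per ray = points_per_ray - 1
        assert mesh.spec.points_per_ray - 1 == 9

    def test_slope_zero_ray_fractions(self):
        mesh = relative_mesh(radial_bowl, ORIGIN_PEAK)
        r0 = mesh.points[mesh.points["ray_index"] == 0].sort_values("position_index")
        assert np.allclose(r0["xw"], -4.2 * np.arange(1, 11))
        assert np.allclose(r0["xn"], 0.0)

    def test_points_inside_plane_for_published_surfaces(self, grid):
        for label, surf in EXPERIMENTAL_SURFACES.items():
            peak = find_peak(surface_grid(surf, grid), grid)
            trough = label == "Mo17"
            mesh = relative_mesh(surf, peak, grid=grid, trough=trough,
                                 surface_label=label)
            (wlo, whi), (nlo, nhi) = grid.water_interval, grid.nitrogen_interval
            pts = mesh.points
            assert pts["xw"].between(wlo - 1e-9, whi + 1e-9).all(), label
            assert pts["xn"].between(nlo - 1e-9, nhi + 1e-9).all(), label

    def test_translation_equivariance(self):
        """Translating the surface and the evaluation plane together by
        (dw, dn) translates every mesh point by exactly that vector."""
        from surfaceqtl.surfaces import EvaluationGrid

        def shifted(dx, dn):
            def f(xw, xn):
                return -((np.asarray(xw, float) - dx) ** 2
                         + (np.asarray(xn, float) - dn) ** 2)
            return f

        dw, dn = 3.0, 1.5
        g0 = DEFAULT_GRID
        g1 = EvaluationGrid((-42.0 + dw, 42.0 + dw), (-7.5 + dn, 7.5 + dn), 0.5)
        m0 = relative_mesh(shifted(20.0, 2.0),
                           PeakLocation(20.0, 2.0, 0.0, False), grid=g0)
        m1 = relative_mesh(shifted(20.0 + dw, 2.0 + dn),
                           PeakLocation(20.0 + dw, 2.0 + dn, 0.0, False), grid=g1)
        assert np.allclose(m1.points["xw"] - m0.points["xw"], dw)
        assert np.allclose(m1.points["xn"] - m0.points["xn"], dn)
        assert np.allclose(m1.points["z"], m0.points["z"])

    def test_trough_rays_run_rightward_with_negated_slopes(self):
        peak = PeakLocation(-42.0, 7.5, 0.0, True)
        mesh = relative_mesh(radial_bowl, peak, trough=True)
        for ray_idx, slope in enumerate(DEFAULT_RAY_SLOPES):
            ray = mesh.points[mesh.points["ray_index"] == ray_idx]
            assert (ray["xw"] > -42.0).all()
            if slope > 0:
                assert (ray["xn"] < 7.5).all()  # descending in nitrogen

    def test_zero_length_ray_flagged(self):
        peak = PeakLocation(-42.0, -7.5, 0.0, True)  # dome rays blocked
        mesh = relative_mesh(radial_bowl, peak)
        assert (mesh.points["flag"] == "collapsed").all()

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            relative_mesh(radial_bowl, PeakLocation(99.0, 0.0, 0.0, False))


class TestAbsoluteMesh:
    def test_radial_paraboloid_contour_radius(self):
        """On z = -(xw^2 + xn^2) the f = 0.25 contour along the water ray
        clipped at 42 sits at planar radius 21."""
        spec = MeshSpec(flavor="absolute", ray_angles=(0.0,),
                        contour_fractions=(0.25,))
        mesh = absolute_mesh(radial_bowl, ORIGIN_PEAK, np.array([1.0, 0.0]),
                             spec=spec)
        pt = mesh.points.iloc[0]
        assert np.hypot(pt["xw"], pt["xn"]) == pytest.approx(21.0, abs=1e-4)

    def test_include_peak_changes_count_by_one(self):
        spec = MeshSpec(flavor="absolute")
        m0 = absolute_mesh(radial_bowl, ORIGIN_PEAK, np.array([1.0, 0.0]), spec=spec)
        spec1 = MeshSpec(flavor="absolute", include_peak=True)
        m1 = absolute_mesh(radial_bowl, ORIGIN_PEAK, np.array([1.0, 0.0]), spec=spec1)
        assert len(m1.points) == len(m0.points) + 1

    def test_contour_self_consistency_on_published_surface(self, grid):
        surf = EXPERIMENTAL_SURFACES["B73"]
        peak = find_peak(surface_grid(surf, grid), grid)
        from surfaceqtl.mesh import local_axis as la
        mesh = absolute_mesh(surf, peak, la(surf), grid=grid, surface_label="B73")
        ok = mesh.points[mesh.points["flag"] == ""]
        assert len(ok) == len(mesh.spec.ray_angles) * len(mesh.spec.contour_fractions)
        # stored z agrees with the evaluator at the stored coordinates
        assert np.allclose(ok["z"], surf(ok["xw"].to_numpy(), ok["xn"].to_numpy()),
                           atol=1e-9)
        # and each point's z hits its ray's contour target to the bisection
        # tolerance: reconstruct targets from the clipped ray ends
        zpeak = float(surf(peak.xw, peak.xn))
        for ray_idx, grp in ok.groupby("ray_index"):
            angle = mesh.spec.ray_angles[int(ray_idx)]
            rad = np.deg2rad(angle)
            rot = np.array([[np.cos(rad), -np.sin(rad)],
                            [np.sin(rad), np.cos(rad)]])
            direction = rot @ mesh.local_axis
            from surfaceqtl.mesh import _clip_length
            t_end = _clip_length(peak, direction, grid)
            z_end = float(surf(peak.xw + t_end * direction[0],
                               peak.xn + t_end * direction[1]))
            for _, pt in grp.iterrows():
                f = mesh.spec.contour_fractions[int(pt["position_index"]) - 1]
                target = zpeak - f * (zpeak - z_end)
                assert abs(pt["z"] - target) < 1e-6

    def test_degenerate_flat_ray_flags_missing_intersection(self):
        """A ray along which z never leaves the peak level has no usable
        contour crossing; the (ray, contour) pair is flagged, not invented."""
        def flat(xw, xn):
            return np.zeros_like(np.asarray(xw, float))

        spec = MeshSpec(flavor="absolute", ray_angles=(0.0,),
                        contour_fractions=(0.5,))
        mesh = absolute_mesh(flat, ORIGIN_PEAK, np.array([1.0, 0.0]), spec=spec)
        assert (mesh.points["flag"] == "missing").all()
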