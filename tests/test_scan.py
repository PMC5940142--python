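"""Mixed-model surface fitting, the marker F-scan, and p-value machinery."""

import numpy as np
import pandas as pd
import pytest

from surfaceqtl.exceptions import InvalidArgumentError
from surfaceqtl.scan import (
    ScanResult,
    VarianceComponents,
    adjust_pvalues,
    call_qtl,
    fit_surface,
    marker_scan,
    sidak_threshold,
    simes_combine,
    simes_smooth,
)
from surfaceqtl.surfaces import QuadraticSurface, evaluate_quadratic
from surfaceqtl.synthetic import (
    KinshipMatrix,
    build_design,
    compute_kinship,
    simulate_genotypes,
    simulate_phenotypes,
)

TRUTH = QuadraticSurface("truth", beta1=0.23, beta2=0.99, beta3=-0.006,
                         beta4=-0.19, beta5=0.026, ell=32.0)


def _quadratic_phenotypes(genotypes, design, surface, sigma_resid=0.0, seed=0):
    """Phenotypes whose mean is exactly a quadratic surface."""
    ph = simulate_phenotypes(genotypes, design, baseline=0.0, sigma_line=0.0,
                             sigma_resid=sigma_resid, seed=seed)
    mean = evaluate_quadratic(surface, ph["xw"].to_numpy(), ph["xn"].to_numpy())
    noise = ph["diff_height_cm"].to_numpy()  # already N(0, sigma^2)
    ph["diff_height_cm"] = mean + noise
    ph["final_height_cm"] = ph["initial_height_cm"] + ph["diff_height_cm"]
    return ph


class TestFitSurface:
    def test_noiseless_recovery(self, small_population):
        genotypes, kinship, design, _ = small_population
        ph = _quadratic_phenotypes(genotypes, design, TRUTH)
        fit = fit_surface(ph, kinship)
        got = fit.coefficients["all"]
        for attr in ("beta1", "beta2", "beta3", "beta4", "beta5", "ell"):
            assert getattr(got, attr) == pytest.approx(getattr(TRUTH, attr), abs=1e-8)
        assert fit.weighted_rss == pytest.approx(0.0, abs=1e-12)
        assert fit.n_fixed_params == 6

    def test_gls_reduces_to_ols_without_line_variance(self, small_population):
        """With sigma_line = 0 the REML fit collapses to OLS: coefficients
        match an independent normal-equations OLS oracle."""
        genotypes, _, design, _ = small_population
        kinship = KinshipMatrix.identity(genotypes.line_ids)
        ph = _quadratic_phenotypes(genotypes, design, TRUTH, sigma_resid=2.0, seed=5)
        fit = fit_surface(ph, kinship)
        assert fit.variance_components.sigma_line2 == pytest.approx(
            0.0, abs=0.05 * fit.variance_components.sigma_resid2)
        xw, xn = ph["xw"].to_numpy(), ph["xn"].to_numpy()
        X = np.column_stack([xw, xn, xw**2, xn**2, xw * xn, np.ones_like(xw)])
        y = ph["diff_height_cm"].to_numpy()
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        got = fit.coefficients["all"]
        fitted = [got.beta1, got.beta2, got.beta3, got.beta4, got.beta5, got.ell]
        # the REML ratio is ~0 but not exactly 0; oracle agreement is loose-tight
        assert np.allclose(fitted, beta_ols, atol=1e-6, rtol=1e-4)

    def test_allele_groups_from_same_surface_agree(self, small_population):
        genotypes, kinship, design, _ = small_population
        ph = _quadratic_phenotypes(genotypes, design, TRUTH, sigma_resid=1.0, seed=6)
        split = pd.Series(genotypes.marker_calls("m03_005"),
                          index=genotypes.line_ids)
        fit = fit_surface(ph, kinship, allele_split=split)
        assert fit.n_fixed_params == 12
        b73, mo17 = fit.coefficients["B73"], fit.coefficients["Mo17"]
        assert b73.ell == pytest.approx(mo17.ell, abs=1.0)
        assert b73.beta2 == pytest.approx(mo17.beta2, abs=0.5)

    def test_variance_components_recovered(self):
        """REML recovers (sigma_line^2, sigma_resid^2) = (4, 1) within 30%
        on average across seeds under the default design."""
        est = []
        for seed in range(20):
            g = simulate_genotypes(89, chromosomes=((5, 100.0),), seed=100 + seed)
            k = compute_kinship(g)
            ph = simulate_phenotypes(g, build_design(), sigma_line=2.0,
                                     sigma_resid=1.0, kinship=k, seed=200 + seed)
            fit = fit_surface(ph, k)
            vc = fit.variance_components
            est.append((vc.sigma_line2, vc.sigma_resid2))
        mean_line2, mean_resid2 = np.mean(est, axis=0)
        assert abs(mean_line2 - 4.0) < 0.3 * 4.0
        assert abs(mean_resid2 - 1.0) < 0.3 * 1.0


class TestMarkerScan:
    def test_nesting_and_nonnegative_F(self, small_population):
        genotypes, kinship, _, phenotypes = small_population
        scan = marker_scan(phenotypes, genotypes, kinship)
        ok = scan.markers[~scan.markers["skipped"]]
        assert (ok["F"] >= 0).all()
        assert ok["raw_p"].between(0, 1).all()
        assert len(ok) > 0

    def test_identical_allele_surfaces_zero_noise_give_F_zero(self, small_population):
        genotypes, kinship, design, _ = small_population
        ph = _quadratic_phenotypes(genotypes, design, TRUTH)
        scan = marker_scan(ph, genotypes, kinship)
        ok = scan.markers[~scan.markers["skipped"]]
        assert np.allclose(ok["F"], 0.0)
        assert np.allclose(ok["raw_p"], 1.0)

    def test_causal_marker_has_smallest_p(self, small_population):
        genotypes, kinship, _, phenotypes = small_population
        scan = marker_scan(phenotypes, genotypes, kinship)
        best = scan.markers.loc[scan.markers["raw_p"].idxmin(), "marker_id"]
        assert best == "m02_004"

    def test_missing_calls_drop_lines_per_marker(self):
        g = simulate_genotypes(60, chromosomes=((6, 120.0),), seed=21,
                               missing_rate=0.08)
        k = compute_kinship(g)
        ph = simulate_phenotypes(g, build_design(), sigma_line=1.0,
                                 sigma_resid=2.0, kinship=k, seed=22)
        scan = marker_scan(ph, g, k)
        ok = scan.markers[~scan.markers["skipped"]]
        assert (ok["n_obs"] < len(ph)).any()       # some markers lost lines
        assert ok["raw_p"].between(0, 1).all()


class TestPValues:
    def test_simes_combination_hand_example(self):
        assert simes_combine([0.03, 0.01, 0.02]) == pytest.approx(0.03)

    def test_window_of_one_returns_raw(self):
        df = pd.DataFrame({
            "marker_id": list("abc"), "chromosome": [1, 1, 1],
            "order": [0, 1, 2], "raw_p": [0.2, 0.01, 0.9],
            "skipped": [False] * 3,
        })
        scan = ScanResult(markers=df, variance_components=VarianceComponents(0, 1))
        simes_smooth(scan, window=1)
        assert np.allclose(scan.markers["smoothed_p"], [0.2, 0.01, 0.9])

    def test_all_ones_stay_one_and_windows_truncate(self):
        df = pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(7)],
            "chromosome": [1] * 4 + [2] * 3,
            "order": [0, 1, 2, 3, 0, 1, 2], "raw_p": [1.0] * 7,
            "skipped": [False] * 7,
        })
        scan = ScanResult(markers=df, variance_components=VarianceComponents(0, 1))
        simes_smooth(scan, window=5)
        assert np.allclose(scan.markers["smoothed_p"], 1.0)

    def test_even_window_rejected(self):
        df = pd.DataFrame({"marker_id": ["a"], "chromosome": [1], "order": [0],
                           "raw_p": [0.5], "skipped": [False]})
        scan = ScanResult(markers=df, variance_components=VarianceComponents(0, 1))
        with pytest.raises(InvalidArgumentError):
            simes_smooth(scan, window=4)

    @pytest.mark.parametrize("m, expected", [(1, 0.05), (2, 0.025321)])
    def test_sidak_threshold(self, m, expected):
        assert sidak_threshold(0.05, m) == pytest.approx(expected, abs=1e-6)
        assert sidak_threshold(0.05, m) >= 0.05 / m  # never below Bonferroni

    def test_bh_step_up_hand_example(self):
        adj = adjust_pvalues([0.01, 0.04, 0.03], method="fdr")
        assert np.allclose(adj, [0.03, 0.04, 0.04])
        assert np.all(np.diff(np.sort(adj)) >= 0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(InvalidArgumentError):
            adjust_pvalues([0.5], method="sidak", alpha=1.5)


class TestCallQTL:
    def _scan_from_pattern(self, sig_pattern, chromosome=1):
        n = len(sig_pattern)
        # smoothed p-values chosen so the Sidak threshold splits the pattern
        p = np.where(np.asarray(sig_pattern, bool), 1e-6, 0.5)
        df = pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(n)],
            "chromosome": [chromosome] * n, "order": range(n),
            "raw_p": p, "smoothed_p": p, "skipped": [False] * n,
        })
        return ScanResult(markers=df, variance_components=VarianceComponents(0, 1))

    def test_adjacent_runs_merge_into_intervals(self):
        scan = self._scan_from_pattern([0, 1, 1, 0, 1])
        intervals = call_qtl(scan, criterion="sidak", alpha=0.05)
        assert [iv.n_markers for iv in intervals] == [2, 1]
        assert intervals[0].start_marker == "m1"
        assert intervals[0].end_marker == "m2"
        assert intervals[1].best_marker == "m4"

    def test_no_significant_markers_empty(self):
        scan = self._scan_from_pattern([0, 0, 0])
        assert call_qtl(scan, criterion="fdr", alpha=0.05) == []

    def test_planted_qtl_interval_contains_causal_marker(self, small_population):
        genotypes, kinship, _, phenotypes = small_population
        scan = marker_scan(phenotypes, genotypes, kinship)
        simes_smooth(scan)
        intervals = call_qtl(scan, criterion="sidak", alpha=0.05)
        chrom2 = [iv for iv in intervals if iv.chromosome == 2]
        assert any(iv.start_marker <= "m02_004" <= iv.end_marker for iv in chrom2)
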