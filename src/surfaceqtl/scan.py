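"""Kinship-weighted mixed-model genome scan for response-surface QTL.

The phenotype model for the growth record of line *i* under water ``xw``
and nitrogen ``xn`` is

    z = b1*xw + b2*xn + b3*xw^2 + b4*xn^2 + b5*xw*xn + mu + alpha_i + eps,

with a line random effect ``alpha ~ N(0, sigma_line^2 * K)`` structured by
the kinship matrix K and i.i.d. residuals ``eps ~ N(0, sigma_resid^2)``.
Variance components are estimated once by REML on the *all-inclusive*
model (a single pooled surface), using the spectral decomposition of
``Z K Z'`` so that each REML evaluation and all subsequent generalized
least squares (GLS) fits cost O(n * L) rather than O(n^3).

The scan then compares, marker by marker, the pooled surface (6 fixed
parameters) against a two-group model fitting a separate surface to the
B73-allele and Mo17-allele lines (12 parameters) under the same fitted
covariance, via

    F = ((RSS0 - RSS1) / 6) / (RSS1 / (n - 12)),

where the RSS are whitened (GLS) residual sums of squares on the marker's
non-missing observations. Raw p-values come from the F(6, n-12)
distribution; they are then smoothed along the map with a sliding Simes
window, adjusted for multiplicity (Benjamini-Hochberg FDR or a Sidak
experiment-wise threshold), and maximal runs of adjacent significant
markers are merged into QTL intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    EmptyScanError,
    InvalidArgumentError,
    ModelSpecificationError,
    RankDeficiencyError,
)
from .surfaces import QuadraticSurface
from .synthetic import B73, MISSING, MO17, GenotypeMatrix, KinshipMatrix

__all__ = [
    "VarianceComponents", "SurfaceFit", "ScanResult", "QTLInterval",
    "KinshipGLS", "fit_surface", "marker_scan", "simes_smooth",
    "adjust_pvalues", "sidak_threshold", "call_qtl",
]

N_SURFACE_PARAMS = 6  # b1, b2, b3, b4, b5, intercept


@dataclass(frozen=True)
class VarianceComponents:
    sigma_line2: float
    sigma_resid2: float

    @property
    def ratio(self) -> float:
        """sigma_line^2 / sigma_resid^2 (the profiled REML parameter)."""
        if self.sigma_resid2 == 0:
            return math.inf
        return self.sigma_line2 / self.sigma_resid2


@dataclass
class SurfaceFit:
    """A fitted quadratic surface model (pooled, or split by marker allele)."""

    coefficients: dict[str, QuadraticSurface]
    weighted_rss: float
    n_obs: int
    n_fixed_params: int
    variance_components: VarianceComponents


@dataclass(frozen=True)
class QTLInterval:
    chromosome: int
    start_marker: str
    end_marker: str
    best_marker: str
    best_p: float
    n_markers: int


@dataclass
class ScanResult:
    """Per-marker scan statistics plus called QTL intervals.

    ``markers`` columns: marker_id, chromosome, order, n_obs, F, raw_p,
    skipped, and (after smoothing/adjustment) smoothed_p, fdr_p, sidak_sig.
    """

    markers: pd.DataFrame
    variance_components: VarianceComponents
    intervals: list[QTLInterval] = field(default_factory=list)


def _surface_design(xw: np.ndarray, xn: np.ndarray) -> np.ndarray:
    return np.column_stack([xw, xn, xw**2, xn**2, xw * xn, np.ones_like(xw)])


def _check_rank(X: np.ndarray, context: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(f"{context}: design matrix is rank deficient")


class KinshipGLS:
    """Whitening engine for V = sigma_e^2 * (I + lambda * Z K Z').

    Uses K = U diag(w) U' and the thin SVD of M = Z U diag(sqrt(w)) so that
    Z K Z' = P diag(s^2) P' with orthonormal P (n x L). Whitening by
    (I + lambda Z K Z')^(-1/2) is then a rank-L update.
    """

    def __init__(self, line_index: np.ndarray, kinship: KinshipMatrix,
                 ridge: float = 1e-6):
        K = kinship.psd_values(ridge)
        w, U = np.linalg.eigh(K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ModelSpecificationError("kinship matrix is not positive semi-definite")
        root = U * np.sqrt(np.clip(w, 0.0, None))
        M = root[line_index]  # n x L
        P, s, _ = np.linalg.svd(M, full_matrices=False)
        keep = s > s.max() * 1e-12 if s.size else np.zeros(0, dtype=bool)
        self.P = P[:, keep]
        self.s2 = s[keep] ** 2
        self.n = M.shape[0]

    def whiten(self, A: np.ndarray, lam: float) -> np.ndarray:
        """Apply (I + lam * Z K Z')^(-1/2) to the columns of A."""
        if lam == 0.0 or self.s2.size == 0:
            return A
        f = 1.0 / np.sqrt(1.0 + lam * self.s2)
        PtA = self.P.T @ A
        return A + self.P @ ((f - 1.0)[:, None] * PtA if A.ndim == 2
                             else (f - 1.0) * PtA)

    def logdet(self, lam: float) -> float:
        return float(np.sum(np.log1p(lam * self.s2)))

    def reml(self, X: np.ndarray, y: np.ndarray) -> tuple[float, VarianceComponents]:
        """Profile-REML estimate of lambda and the variance components."""
        n, p = X.shape

        def neg2_reml(log_lam: float) -> float:
            lam = math.exp(log_lam)
            Xw = self.whiten(X, lam)
            yw = self.whiten(y, lam)
            beta, rss = _ols(Xw, yw)
            sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
            if sign <= 0 or rss <= 0:
                return math.inf
            return (n - p) * math.log(rss) + self.logdet(lam) + logdet_xx

        # coarse bracket on log-lambda, then local refinement
        grid = np.linspace(-12.0, 8.0, 41)
        vals = [neg2_reml(g) for g in grid]
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(neg2_reml, bounds=(lo, hi), method="bounded")
        lam = math.exp(res.x)
        # compare against the boundary lambda -> 0 (no line variance)
        if neg2_reml(-30.0) <= res.fun:
            lam = 0.0
        Xw = self.whiten(X, lam)
        yw = self.whiten(y, lam)
        _, rss = _ols(Xw, yw)
        sigma_e2 = rss / (n - p)
        return lam, VarianceComponents(sigma_line2=lam * sigma_e2, sigma_resid2=sigma_e2)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficiencyError("rank-deficient design in GLS fit")
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _coeffs_to_surface(label: str, beta: np.ndarray) -> QuadraticSurface:
    b1, b2, b3, b4, b5, ell = (float(v) for v in beta)
    return QuadraticSurface(label=label, beta1=b1, beta2=b2, beta3=b3,
                            beta4=b4, beta5=b5, ell=ell)


def _prepare(phenotypes: pd.DataFrame, kinship: KinshipMatrix):
    needed = {"line_id", "xw", "xn", "diff_height_cm"}
    if not needed.issubset(phenotypes.columns):
        raise InvalidArgumentError(
            "phenotype table must carry line_id, xw, xn, diff_height_cm "
            "(run validate_phenotypes/read_phenotypes first)"
        )
    index = {lid: i for i, lid in enumerate(kinship.line_ids)}
    unknown = set(phenotypes["line_id"]) - set(index)
    if unknown:
        raise InvalidArgumentError(f"lines missing from kinship: {sorted(unknown)[:5]}")
    li = phenotypes["line_id"].map(index).to_numpy()
    X = _surface_design(phenotypes["xw"].to_numpy(float), phenotypes["xn"].to_numpy(float))
    y = phenotypes["diff_height_cm"].to_numpy(float)
    return li, X, y


def fit_surface(
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrix,
    allele_split: pd.Series | None = None,
    *,
    variance_components: VarianceComponents | None = None,
    engine: KinshipGLS | None = None,
) -> SurfaceFit:
    """Fit the pooled quadratic surface, or one surface per marker allele.

    Variance components are estimated by REML on the pooled model unless
    supplied (the scan estimates them once and reuses them for every
    marker model so the residual sums of squares stay comparable).
    ``allele_split`` maps line_id -> allele code (B73/MO17); lines with a
    missing call are excluded from the split fit.
    """
    li, X, y = _prepare(phenotypes, kinship)
    if engine is None:
        engine = KinshipGLS(li, kinship)
    if variance_components is None:
        _check_rank(X, "all-inclusive model")
        lam, vc = engine.reml(X, y)
    else:
        vc = variance_components
        lam = vc.ratio

    if allele_split is None:
        if len(y) <= N_SURFACE_PARAMS:
            raise InvalidArgumentError("too few observations for the pooled surface")
        Xw, yw = engine.whiten(X, lam), engine.whiten(y, lam)
        _check_rank(Xw, "all-inclusive model")
        beta, rss = _ols(Xw, yw)
        return SurfaceFit(
            coefficients={"all": _coeffs_to_surface("all", beta)},
            weighted_rss=rss, n_obs=len(y), n_fixed_params=N_SURFACE_PARAMS,
            variance_components=vc,
        )

    alleles = phenotypes["line_id"].map(allele_split).to_numpy()
    keep = np.isin(alleles, (B73, MO17))
    sub = phenotypes.loc[keep]
    li_sub = li[keep]
    sub_engine = engine if keep.all() else KinshipGLS(li_sub, kinship)
    Xs, ys, alle = X[keep], y[keep], alleles[keep]
    for code, name in ((B73, "B73"), (MO17, "Mo17")):
        if (alle == code).sum() <= N_SURFACE_PARAMS:
            raise InvalidArgumentError(f"too few observations in allele group {name}")
    X12 = np.hstack([Xs * (alle == B73)[:, None], Xs * (alle == MO17)[:, None]])
    Xw, yw = sub_engine.whiten(X12, lam), sub_engine.whiten(ys, lam)
    _check_rank(Xw, "marker model")
    beta, rss = _ols(Xw, yw)
    return SurfaceFit(
        coefficients={
            "B73": _coeffs_to_surface("B73", beta[:6]),
            "Mo17": _coeffs_to_surface("Mo17", beta[6:]),
        },
        weighted_rss=rss, n_obs=int(keep.sum()), n_fixed_params=2 * N_SURFACE_PARAMS,
        variance_components=vc,
    )


def marker_scan(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    *,
    min_class_obs: int = 10,
) -> ScanResult:
    """Scan every marker with the surface-difference F-test.

    For each marker, observations from lines with a missing call are
    dropped and the pooled model's RSS is recomputed on the same reduced
    observation set, so the F-test compares nested models on identical
    data. Markers where either allele class has fewer than
    ``min_class_obs`` phenotype records are skipped and flagged.
    """
    li, X, y = _prepare(phenotypes, kinship)
    n_total = len(y)
    engine = KinshipGLS(li, kinship)
    _check_rank(X, "all-inclusive model")
    lam, vc = engine.reml(X, y)
    Xw_full, yw_full = engine.whiten(X, lam), engine.whiten(y, lam)
    _, rss0_full = _ols(Xw_full, yw_full)

    line_order = {lid: i for i, lid in enumerate(genotypes.line_ids)}
    geno_row = phenotypes["line_id"].map(line_order)
    if geno_row.isna().any():
        raise InvalidArgumentError("phenotype lines missing from genotype matrix")
    geno_row = geno_row.to_numpy(int)

    records = []
    for order, (_, mk) in enumerate(genotypes.markers.iterrows()):
        calls = genotypes.calls[:, order][geno_row]
        present = calls != MISSING
        n_b73 = int((calls == B73).sum())
        n_mo17 = int((calls == MO17).sum())
        rec = {
            "marker_id": mk["marker_id"], "chromosome": int(mk["chromosome"]),
            "order": order, "position_cM": float(mk["position_cM"]),
            "n_obs": int(present.sum()), "n_b73": n_b73, "n_mo17": n_mo17,
            "F": np.nan, "raw_p": np.nan, "skipped": True,
        }
        if min(n_b73, n_mo17) >= min_class_obs and rec["n_obs"] > 2 * N_SURFACE_PARAMS + 1:
            if present.all():
                Xw, yw, rss0 = Xw_full, yw_full, rss0_full
                alle = calls
            else:
                sub_engine = KinshipGLS(li[present], kinship)
                Xw = sub_engine.whiten(X[present], lam)
                yw = sub_engine.whiten(y[present], lam)
                _, rss0 = _ols(Xw, yw)
                alle = calls[present]
            X12 = np.hstack([Xw * 0.0, Xw * 0.0])
            mask_b = (alle == B73)[:, None]
            X12[:, :6] = Xw * mask_b
            X12[:, 6:] = Xw * ~mask_b
            try:
                _, rss1 = _ols(X12, yw)
            except RankDeficiencyError:
                records.append(rec)
                continue
            n = len(yw)
            df1, df2 = N_SURFACE_PARAMS, n - 2 * N_SURFACE_PARAMS
            num = max(rss0 - rss1, 0.0)
            scale = max(rss0, 1.0)
            if rss1 <= 1e-12 * scale:  # both models fit exactly
                F = 0.0 if num <= 1e-12 * scale else math.inf
            else:
                F = (num / df1) / (rss1 / df2)
            rec.update(F=F, raw_p=float(stats.f.sf(F, df1, df2)), skipped=False)
        records.append(rec)

    df = pd.DataFrame(records)
    if df.empty or df["skipped"].all():
        raise EmptyScanError("no scannable markers")
    _ = n_total
    return ScanResult(markers=df, variance_components=vc)


def simes_combine(pvalues: np.ndarray) -> float:
    """Simes combination: min over k of (m * p_(k) / k), capped at 1."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = len(p)
    k = np.arange(1, m + 1)
    return float(min(1.0, np.min(m * p / k)))


def simes_smooth(scan: ScanResult, window: int = 5) -> ScanResult:
    """Smooth raw p-values with a sliding Simes window along the map.

    Each marker's window holds up to ``window`` map-adjacent markers
    centered on it, truncated at chromosome ends and never spanning
    chromosomes; skipped markers do not contribute. Adds a ``smoothed_p``
    column (NaN for skipped markers) and returns the same ScanResult.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidArgumentError("window must be a positive odd integer")
    df = scan.markers
    half = window // 2
    smoothed = np.full(len(df), np.nan)
    for _, grp in df.groupby("chromosome", sort=False):
        if np.any(np.diff(grp["order"].to_numpy()) <= 0):
            raise InvalidArgumentError("markers not map-ordered within chromosome")
        idx = grp.index.to_numpy()
        p = grp["raw_p"].to_numpy(float)
        for j in range(len(idx)):
            if np.isnan(p[j]):
                continue
            lo, hi = max(0, j - half), min(len(idx), j + half + 1)
            win = p[lo:hi]
            win = win[~np.isnan(win)]
            smoothed[df.index.get_loc(idx[j])] = simes_combine(win)
    df["smoothed_p"] = smoothed
    return scan


def sidak_threshold(alpha: float, m: int) -> float:
    """Experiment-wise Sidak per-test threshold 1 - (1 - alpha)^(1/m)."""
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def adjust_pvalues(pvalues, method: str = "fdr", alpha: float = 0.05):
    """Multiplicity adjustment.

    ``method='fdr'`` returns Benjamini-Hochberg step-up adjusted p-values;
    ``method='sidak'`` returns ``(threshold, flags)`` with the per-test
    Sidak threshold and boolean significance flags.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise InvalidArgumentError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if method == "fdr":
        return multipletests(p, alpha=alpha, method="fdr_bh")[1]
    if method == "sidak":
        thr = sidak_threshold(alpha, p.size)
        return thr, p <= thr
    raise InvalidArgumentError(f"unknown method {method!r}")


def call_qtl(scan: ScanResult, criterion: str = "sidak", alpha: float = 0.05) -> list[QTLInterval]:
    """Merge maximal runs of map-adjacent significant markers into intervals.

    Significance is evaluated on the Simes-smoothed p-values: under
    ``criterion='sidak'`` a marker is significant when smoothed_p falls
    below the experiment-wise Sidak threshold; under ``'fdr'`` when its
    BH-adjusted smoothed_p <= alpha. Adds ``fdr_p``/``sidak_sig`` columns,
    stores the intervals on the ScanResult, and returns them.
    """
    df = scan.markers
    if "smoothed_p" not in df.columns:
        raise InvalidArgumentError("run simes_smooth before call_qtl")
    if criterion not in ("sidak", "fdr"):
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")
    usable = (~df["smoothed_p"].isna()).to_numpy()
    p = df.loc[usable, "smoothed_p"].to_numpy(float)
    sig = np.zeros(len(df), dtype=bool)
    fdr_p = np.full(len(df), np.nan)
    sidak_sig = np.zeros(len(df), dtype=bool)
    if usable.any():
        fdr_p[usable] = adjust_pvalues(p, method="fdr", alpha=alpha)
        _thr, sidak_sig[usable] = adjust_pvalues(p, method="sidak", alpha=alpha)
        sig[usable] = sidak_sig[usable] if criterion == "sidak" else fdr_p[usable] <= alpha
    df["fdr_p"] = fdr_p
    df["sidak_sig"] = sidak_sig

    intervals: list[QTLInterval] = []
    for chrom, grp in df.groupby("chromosome", sort=False):
        flags = sig[grp.index.to_numpy()]
        run_start = None
        rows = grp.reset_index(drop=True)
        for j in range(len(rows) + 1):
            on = j < len(rows) and flags[j]
            if on and run_start is None:
                run_start = j
            elif not on and run_start is not None:
                run = rows.iloc[run_start:j]
                best = run.loc[run["smoothed_p"].idxmin()]
                intervals.append(QTLInterval(
                    chromosome=int(chrom),
                    start_marker=str(run.iloc[0]["marker_id"]),
                    end_marker=str(run.iloc[-1]["marker_id"]),
                    best_marker=str(best["marker_id"]),
                    best_p=float(best["smoothed_p"]),
                    n_markers=len(run),
                ))
                run_start = None
    scan.intervals = intervals
    return intervals
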