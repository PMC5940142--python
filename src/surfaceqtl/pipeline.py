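"""End-to-end pipeline: simulate -> scan -> peaks -> producing fits -> shapes.

Every stage is a thin call into the library; the driver only sequences
stages, writes their artifacts under the output directory, and logs one
structured line per stage. Output is deterministic given the config's
seed. Any stage failure aborts with the stage name and a machine-readable
error code wrapped in :class:`~surfaceqtl.exceptions.PipelineError`.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .config import PipelineConfig
from .exceptions import PipelineError, SurfaceQTLError
from .mesh import MeshSpec
from .producing import fit_producing
from .scan import call_qtl, marker_scan, simes_smooth
from .similarity import (
    admit_simulated_surface,
    build_relative_meshes,
    compare_all,
)
from .surfaces import (
    EvaluationGrid,
    classify_shape,
    dominant_curvature_sign,
    find_peak,
    sign_pattern,
    surface_grid,
)
from .synthetic import (
    build_design,
    compute_kinship,
    simulate_genotypes,
    simulate_phenotypes,
)
from .tables import EXAMPLE_DOMED_PARAMS, EXAMPLE_TROUGH_PARAMS

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(repr(sorted(asdict(config).items())).encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except SurfaceQTLError as err:
                code = type(err).__name__
                raise PipelineError(name, code, str(err)) from err
            logger.info("stage=%s status=ok", name)
            return out
        return wrapped
    return deco


@_stage("inputs")
def _load_or_simulate(config: PipelineConfig):
    if config.genotype_path and config.map_path:
        genotypes = sio.read_genotypes(config.genotype_path, config.map_path)
    else:
        chroms = tuple(
            (config.markers_per_chromosome, config.chromosome_length_cm)
            for _ in range(config.n_chromosomes)
        )
        genotypes = simulate_genotypes(
            config.n_lines, chroms, config.expansion_factor,
            seed=config.seed, missing_rate=config.missing_rate,
        )
    design = build_design(config.water_levels, config.nitrogen_levels,
                          reps=(config.corner_reps, config.center_reps))
    if config.kinship_path:
        kinship = sio.read_kinship(config.kinship_path)
    else:
        kinship = compute_kinship(genotypes)
    if config.phenotype_path:
        phenotypes = sio.read_phenotypes(config.phenotype_path)
    else:
        causal = {}
        if config.causal_marker:
            causal[config.causal_marker] = (EXAMPLE_DOMED_PARAMS, EXAMPLE_TROUGH_PARAMS)
        phenotypes = simulate_phenotypes(
            genotypes, design, causal_spec=causal, baseline=config.baseline_cm,
            sigma_line=config.sigma_line, sigma_resid=config.sigma_resid,
            kinship=kinship, seed=config.seed + 1,
        )
    return genotypes, design, kinship, phenotypes


@_stage("scan")
def _scan(phenotypes, genotypes, kinship, config: PipelineConfig):
    scan = marker_scan(phenotypes, genotypes, kinship,
                       min_class_obs=config.min_class_obs)
    simes_smooth(scan, window=config.simes_window)
    intervals = {}
    for method in config.methods:
        intervals[method] = call_qtl(scan, criterion=method, alpha=config.alpha)
    return scan, intervals


@_stage("surfaces")
def _surface_tables(intervals, phenotypes, kinship, genotypes, config: PipelineConfig, grid):
    """Per-allele surfaces at each called QTL's best marker, plus the pooled
    surface: coefficient, peak and shape tables."""
    from .scan import fit_surface

    rows = []
    surfaces = {}
    pooled = fit_surface(phenotypes, kinship)
    surfaces["all-lines"] = pooled.coefficients["all"]
    best_markers = {iv.best_marker for ivs in intervals.values() for iv in ivs}
    for marker_id in sorted(best_markers):
        calls = pd.Series(
            genotypes.marker_calls(marker_id), index=genotypes.line_ids
        )
        fit = fit_surface(phenotypes, kinship, allele_split=calls,
                          variance_components=pooled.variance_components)
        for allele, surf in fit.coefficients.items():
            surfaces[f"{marker_id}-{allele}"] = surf
    for label, surf in surfaces.items():
        z = surface_grid(surf, grid)
        peak = find_peak(z, grid)
        shape = classify_shape(peak, dominant_curvature_sign(surf, grid),
                               step=grid.step)
        rows.append({
            "label": label, "xw": round(peak.xw, 1), "xn": round(peak.xn, 1),
            "zmax": round(peak.zmax, 1), "on_boundary": peak.on_boundary,
            "category": shape.category, "ambiguous": shape.ambiguous,
        })
    return surfaces, pd.DataFrame(rows)


@_stage("producing-fit")
def _producing_fits(surfaces, grid, config: PipelineConfig):
    spec = MeshSpec(points_per_ray=config.points_per_ray)
    trough_flags = {
        lbl: dominant_curvature_sign(surf, grid) > 0 for lbl, surf in surfaces.items()
    }
    meshes = build_relative_meshes(surfaces, trough_flags, spec=spec, grid=grid)
    params, errors, rows = {}, {}, []
    for lbl, mesh in meshes.items():
        c = 1.0 if trough_flags[lbl] else -1.0
        fit = fit_producing(mesh, c, label=lbl)
        params[lbl] = fit.params
        errors[lbl] = fit.s
        sa, sb, sd, se = sign_pattern(fit.params)
        peak = mesh.peak
        shape = classify_shape(peak, c, step=grid.step)
        rows.append({
            "line": lbl, "a": fit.params.a, "b": fit.params.b, "c": c,
            "d": fit.params.d, "e": fit.params.e, "s": fit.s,
            "sgn_a": sa, "sgn_b": sb, "sgn_d": sd, "sgn_e": se,
            "shape": shape.category,
        })
    return params, errors, meshes, pd.DataFrame(rows)


@_stage("compare")
def _compare(surfaces, params, grid, config: PipelineConfig):
    spec = MeshSpec(points_per_ray=config.points_per_ray)
    trough_flags = {
        lbl: dominant_curvature_sign(surf, grid) > 0 for lbl, surf in surfaces.items()
    }
    exp_meshes = build_relative_meshes(surfaces, trough_flags, spec=spec, grid=grid)
    sim_meshes, excluded = {}, {}
    for lbl, p in params.items():
        mesh, reason = admit_simulated_surface(p, spec=spec, grid=grid,
                                               margin=config.exclusion_margin)
        if mesh is not None:
            sim_meshes[lbl] = mesh
        else:
            excluded[lbl] = reason
            logger.info("stage=compare excluded=%s reason=%r", lbl, reason)
    return compare_all(exp_meshes, sim_meshes, excluded=excluded)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the full pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        stream=sys.stderr)
    logger.info("pipeline config_hash=%s seed=%d numpy=%s pandas=%s",
                _config_hash(config), config.seed, np.__version__, pd.__version__)
    grid = EvaluationGrid(config.water_interval, config.nitrogen_interval,
                          config.grid_step)

    genotypes, design, kinship, phenotypes = _load_or_simulate(config)
    sio.write_genotypes(genotypes, outdir / "genotypes.csv", outdir / "marker_map.csv")
    sio.write_kinship(kinship, outdir / "kinship.csv")
    sio.write_phenotypes(phenotypes, outdir / "phenotypes.csv")

    scan, intervals = _scan(phenotypes, genotypes, kinship, config)
    sio.write_scan(scan, outdir / "scan.tsv")
    for method, ivs in intervals.items():
        sio.write_intervals(ivs, outdir / f"qtl_intervals_{method}.tsv")

    surfaces, peak_table = _surface_tables(intervals, phenotypes, kinship, genotypes,
                                           config, grid)
    sio.write_surfaces(surfaces, outdir / "surface_coefficients.csv")
    peak_table.to_csv(outdir / "surface_peaks.csv", index=False)

    params, errors, meshes, producing_table = _producing_fits(surfaces, grid, config)
    sio.write_producing_params(params, errors, outdir / "producing_params.csv")
    producing_table.to_csv(outdir / "producing_fits.csv", index=False)
    for lbl, mesh in meshes.items():
        sio.write_mesh(mesh, outdir / f"mesh_{lbl.replace('/', '_')}.tsv")

    comparison = _compare(surfaces, params, grid, config)
    comparison.rho.to_csv(outdir / "scores_rho.tsv", sep="\t")
    comparison.theta.to_csv(outdir / "scores_theta.tsv", sep="\t")
    comparison.delta_zr.to_csv(outdir / "scores_delta_zr.tsv", sep="\t")

    try:
        from .plotting import projection_plot, scan_manhattan, score_heatmap

        projection_plot(surfaces, outdir / "projections.png", grid=grid)
        scan_manhattan(scan.markers.dropna(subset=["smoothed_p"]),
                       outdir / "scan.png", alpha_line=config.alpha)
        for name, frame in (("rho", comparison.rho), ("theta", comparison.theta),
                            ("delta_zr", comparison.delta_zr)):
            if not frame.empty:
                score_heatmap(frame, outdir / f"heatmap_{name}.png", title=name)
    except SurfaceQTLError as err:  # pragma: no cover - defensive
        raise PipelineError("plots", type(err).__name__, str(err)) from err

    logger.info("pipeline done outdir=%s", outdir)
    return outdir
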