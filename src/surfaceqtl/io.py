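"""Readers and writers for the package's plain-text data formats.

All data travel as CSV/TSV with documented headers; there is no binary
format in this domain. Genotype calls are coded ``A`` (B73 allele), ``B``
(Mo17 allele) and ``-`` (missing) with a companion marker-map CSV. Raw
stress percentages are auto-recentred on read (water - 50, nitrogen -
7.5) into ``xw``/``xn`` columns, originals preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .mesh import MeshPointSet
from .scan import QTLInterval, ScanResult
from .surfaces import ProducingFunctionParams, QuadraticSurface
from .synthetic import (
    B73,
    MISSING,
    MO17,
    GenotypeMatrix,
    KinshipMatrix,
    PHENOTYPE_COLUMNS,
    validate_phenotypes,
)

__all__ = [
    "read_phenotypes", "write_phenotypes",
    "read_genotypes", "write_genotypes",
    "read_kinship", "write_kinship",
    "read_surfaces", "write_surfaces",
    "read_producing_params", "write_producing_params",
    "write_scan", "write_intervals", "write_mesh",
]

_ALLELE_TO_CHAR = {B73: "A", MO17: "B", MISSING: "-"}
_CHAR_TO_ALLELE = {v: k for k, v in _ALLELE_TO_CHAR.items()}

SURFACE_COLUMNS = ["label", "beta3", "beta4", "beta5", "beta1", "beta2", "ell"]
PRODUCING_COLUMNS = ["label", "a", "b", "c", "d", "e", "s"]


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kw)
    except (ValueError, OSError) as err:
        raise FormatError(f"{path}: {err}") from err


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV; validates the height identity and recentres."""
    df = _read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing phenotype columns {missing}")
    for col in PHENOTYPE_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        if bad.size:
            raise FormatError(f"{path}: non-numeric value in column {col!r}, "
                              f"row {int(bad[0])}")
        df[col] = vals
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(PHENOTYPE_COLUMNS))


def read_genotypes(path, map_path) -> GenotypeMatrix:
    """Read the genotype call CSV (line_id + one column per marker) and its
    marker map (marker_id, chromosome, position_cM)."""
    calls_df = _read_csv(path, dtype=str)
    if calls_df.columns[0] != "line_id":
        raise FormatError(f"{path}: first column must be line_id")
    markers = _read_csv(map_path)
    need = {"marker_id", "chromosome", "position_cM"}
    if not need.issubset(markers.columns):
        raise FormatError(f"{map_path}: needs columns {sorted(need)}")
    marker_cols = list(calls_df.columns[1:])
    mapped = set(markers["marker_id"].astype(str))
    for m in marker_cols:
        if m not in mapped:
            raise FormatError(f"{path}: marker {m!r} absent from map {map_path}")
    markers = markers.set_index("marker_id").loc[marker_cols].reset_index()
    calls = np.empty((len(calls_df), len(marker_cols)), dtype=np.int8)
    for j, m in enumerate(marker_cols):
        col = calls_df[m].fillna("-")
        try:
            calls[:, j] = [_CHAR_TO_ALLELE[v] for v in col]
        except KeyError as err:
            raise FormatError(
                f"{path}: invalid allele code {err.args[0]!r} in marker {m!r}"
            ) from None
    return GenotypeMatrix(
        line_ids=list(calls_df["line_id"]), markers=markers, calls=calls
    )


def write_genotypes(genotypes: GenotypeMatrix, path, map_path) -> None:
    data = {"line_id": genotypes.line_ids}
    for j, m in enumerate(genotypes.markers["marker_id"]):
        data[m] = [_ALLELE_TO_CHAR[int(v)] for v in genotypes.calls[:, j]]
    pd.DataFrame(data).to_csv(path, index=False)
    genotypes.markers.to_csv(map_path, index=False,
                             columns=["marker_id", "chromosome", "position_cM"])


def read_kinship(path) -> KinshipMatrix:
    df = _read_csv(path, index_col=0)
    return KinshipMatrix(line_ids=list(df.index.astype(str)),
                         values=df.to_numpy(float))


def write_kinship(kinship: KinshipMatrix, path) -> None:
    pd.DataFrame(kinship.values, index=kinship.line_ids,
                 columns=kinship.line_ids).to_csv(path)


def read_surfaces(path) -> dict[str, QuadraticSurface]:
    df = _read_csv(path)
    missing = [c for c in SURFACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing surface columns {missing}")
    return {
        str(r["label"]): QuadraticSurface(
            label=str(r["label"]), beta1=float(r["beta1"]), beta2=float(r["beta2"]),
            beta3=float(r["beta3"]), beta4=float(r["beta4"]), beta5=float(r["beta5"]),
            ell=float(r["ell"]),
        )
        for _, r in df.iterrows()
    }


def write_surfaces(surfaces: dict[str, QuadraticSurface], path) -> None:
    rows = [
        {"label": s.label, "beta3": s.beta3, "beta4": s.beta4, "beta5": s.beta5,
         "beta1": s.beta1, "beta2": s.beta2, "ell": s.ell}
        for s in surfaces.values()
    ]
    pd.DataFrame(rows, columns=SURFACE_COLUMNS).to_csv(path, index=False)


def read_producing_params(path) -> tuple[dict[str, ProducingFunctionParams], dict[str, float]]:
    df = _read_csv(path)
    missing = [c for c in PRODUCING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing producing-fit columns {missing}")
    params = {
        str(r["label"]): ProducingFunctionParams(
            label=str(r["label"]), a=float(r["a"]), b=float(r["b"]),
            c=float(r["c"]), d=float(r["d"]), e=float(r["e"]),
        )
        for _, r in df.iterrows()
    }
    s = {str(r["label"]): float(r["s"]) for _, r in df.iterrows()}
    return params, s


def write_producing_params(
    params: dict[str, ProducingFunctionParams], s: dict[str, float], path
) -> None:
    rows = [
        {"label": lbl, "a": p.a, "b": p.b, "c": p.c, "d": p.d, "e": p.e,
         "s": s.get(lbl, np.nan)}
        for lbl, p in params.items()
    ]
    pd.DataFrame(rows, columns=PRODUCING_COLUMNS).to_csv(path, index=False)


def write_scan(scan: ScanResult, path) -> None:
    cols = ["marker_id", "chromosome", "order", "F", "raw_p"]
    for extra in ("smoothed_p", "fdr_p", "sidak_sig"):
        if extra in scan.markers.columns:
            cols.append(extra)
    scan.markers.to_csv(path, sep="\t", index=False, columns=cols)


def write_intervals(intervals: list[QTLInterval], path) -> None:
    rows = [
        {"chrom": iv.chromosome, "start_marker": iv.start_marker,
         "end_marker": iv.end_marker, "best_marker": iv.best_marker,
         "best_p": iv.best_p, "n_markers": iv.n_markers}
        for iv in intervals
    ]
    pd.DataFrame(rows, columns=["chrom", "start_marker", "end_marker",
                                "best_marker", "best_p", "n_markers"]
                 ).to_csv(path, sep="\t", index=False)


def write_mesh(mesh: MeshPointSet, path) -> None:
    """Mesh TSV with a commented header block recording the spec."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# surface={mesh.surface_label} flavor={mesh.flavor}\n")
        fh.write(f"# peak xw={mesh.peak.xw} xn={mesh.peak.xn} zmax={mesh.peak.zmax}\n")
        fh.write(f"# points_per_ray={mesh.spec.points_per_ray} "
                 f"include_peak={mesh.spec.include_peak}\n")
        if mesh.flavor == "relative":
            fh.write(f"# ray_slopes={list(mesh.spec.ray_slopes)}\n")
        else:
            fh.write(f"# ray_angles={list(mesh.spec.ray_angles)} "
                     f"contour_fractions={list(mesh.spec.contour_fractions)}\n")
        mesh.points.to_csv(fh, sep="\t", index=False)
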