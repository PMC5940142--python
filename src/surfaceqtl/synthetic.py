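"""Synthetic recombinant-inbred population, stress design, kinship, phenotypes.

Emulates the study system: 89 recombinant inbred lines (RILs) from an
intermated B73 x Mo17 cross, grown under a face-centered response-surface
design with five drought levels (8, 20, 50, 80, 92 % of full pot weight)
crossed with five nitrogen levels (0, 2.5, 7.5, 12.5, 15 % fertilizer) in
nine combinations, with heavier replication at the design center. The
growth phenotype is the difference between final and initial plant height.

Genotypes are fully homozygous two-state Markov chains along each
chromosome; recombination fractions between adjacent markers come from
Haldane's map function applied to the map distance times an *expansion
factor* (default 4) that stands in for the map expansion produced by the
population's extra intermating generations. Phenotypes decompose as

    diff_height = baseline + sum over causal markers of the allele-matched
                  producing-function value at (xw, xn)
                + alpha_line + eps,

with the line effects ``alpha`` drawn once from N(0, sigma_line^2 * K) for
a kinship matrix K, and ``eps`` i.i.d. N(0, sigma_resid^2). All randomness
flows through one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidArgumentError,
    MissingDataError,
    ModelSpecificationError,
)
from .surfaces import ProducingFunctionParams, evaluate_producing

__all__ = [
    "B73", "MO17", "MISSING",
    "GenotypeMatrix", "StressDesign", "KinshipMatrix",
    "DEFAULT_WATER_LEVELS", "DEFAULT_NITROGEN_LEVELS", "DEFAULT_CHROMOSOMES",
    "WATER_CENTER", "NITROGEN_CENTER", "recenter_water", "recenter_nitrogen",
    "haldane", "simulate_genotypes", "build_design",
    "compute_kinship", "simulate_phenotypes", "validate_phenotypes",
    "PHENOTYPE_COLUMNS",
]

# Allele codes: homozygous B73, homozygous Mo17, missing call.
B73: int = 0
MO17: int = 1
MISSING: int = -1

DEFAULT_WATER_LEVELS: tuple[float, ...] = (8.0, 20.0, 50.0, 80.0, 92.0)
DEFAULT_NITROGEN_LEVELS: tuple[float, ...] = (0.0, 2.5, 7.5, 12.5, 15.0)

# Recentring convention: raw stress percentages shift so the design center
# is the origin, putting water on [-42, 42] and nitrogen on [-7.5, 7.5].
WATER_CENTER: float = 50.0
NITROGEN_CENTER: float = 7.5

#: default simulated genome: 10 chromosomes x 20 markers over 120 cM each
DEFAULT_CHROMOSOMES: tuple[tuple[int, float], ...] = tuple((20, 120.0) for _ in range(10))

PHENOTYPE_COLUMNS = (
    "line_id", "water_pct", "nitrogen_pct",
    "initial_height_cm", "final_height_cm", "diff_height_cm",
)


def recenter_water(water_pct):
    return np.asarray(water_pct, dtype=float) - WATER_CENTER


def recenter_nitrogen(nitrogen_pct):
    return np.asarray(nitrogen_pct, dtype=float) - NITROGEN_CENTER


def haldane(dist_cm) -> np.ndarray:
    """Haldane map function: recombination fraction for a map distance in cM."""
    d = np.asarray(dist_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass
class GenotypeMatrix:
    """Lines x ordered markers allele calls.

    ``calls`` is an int8 matrix with values in {B73, MO17, MISSING};
    ``markers`` has columns marker_id, chromosome, position_cM and is
    strictly ordered by (chromosome, position).
    """

    line_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.markers)):
            raise InvalidArgumentError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        for _, grp in self.markers.groupby("chromosome", sort=False):
            pos = grp["position_cM"].to_numpy(dtype=float)
            if np.any(np.diff(pos) < 0):
                raise InvalidArgumentError(
                    "markers not ordered by map position within chromosome"
                )
        if np.any(np.all(self.calls == MISSING, axis=1)):
            raise InvalidArgumentError("a line has no non-missing calls")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_calls(self, marker_id: str) -> np.ndarray:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise InvalidArgumentError(f"unknown marker {marker_id!r}")
        return self.calls[:, int(idx[0])]


@dataclass(frozen=True)
class StressDesign:
    """The two-stress experimental design: (water %, nitrogen %, replicates)."""

    combinations: tuple[tuple[float, float, int], ...]
    water_levels: tuple[float, ...]
    nitrogen_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        for w, n, r in self.combinations:
            if w not in self.water_levels or n not in self.nitrogen_levels:
                raise InvalidArgumentError(
                    f"combination ({w}, {n}) references non-design levels"
                )
            if r <= 0:
                raise InvalidArgumentError("replicate counts must be positive")

    @property
    def records_per_line(self) -> int:
        return sum(r for *_levels, r in self.combinations)


@dataclass
class KinshipMatrix:
    """Symmetric lines x lines relatedness coefficients in [0, 1]."""

    line_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L = len(self.line_ids)
        if self.values.shape != (L, L):
            raise InvalidArgumentError("kinship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise InvalidArgumentError("kinship matrix not symmetric")

    @classmethod
    def identity(cls, line_ids: list[str]) -> "KinshipMatrix":
        return cls(line_ids=list(line_ids), values=np.eye(len(line_ids)))

    def psd_values(self, ridge: float = 1e-6) -> np.ndarray:
        """Values with a small ridge added to the diagonal (numerical PSD)."""
        return self.values + ridge * np.eye(len(self.line_ids))


def simulate_genotypes(
    n_lines: int,
    chromosomes: tuple[tuple[int, float], ...] = DEFAULT_CHROMOSOMES,
    expansion_factor: float = 4.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    line_prefix: str = "RIL",
) -> GenotypeMatrix:
    """Simulate a homozygous biparental RIL genotype matrix.

    Per line and chromosome, the allele sequence is a two-state Markov
    chain: the first marker is Bernoulli(1/2), and each subsequent marker
    switches allele with probability ``haldane(d * expansion_factor)``
    where ``d`` is the map distance to the previous marker. Chromosomes
    are independent. ``missing_rate`` injects missing calls at random.
    """
    if n_lines < 2:
        raise InvalidArgumentError("n_lines must be >= 2")
    if expansion_factor <= 0:
        raise InvalidArgumentError("expansion_factor must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise InvalidArgumentError("missing_rate must be in [0, 1)")
    for n_markers, length in chromosomes:
        if n_markers < 2 or length < 0:
            raise InvalidArgumentError("each chromosome needs >= 2 markers, length >= 0")

    rng = np.random.default_rng(seed)
    marker_rows = []
    blocks = []
    for chrom_idx, (n_markers, length) in enumerate(chromosomes, start=1):
        pos = np.linspace(0.0, length, n_markers)
        r = haldane(np.diff(pos) * expansion_factor)
        first = rng.integers(0, 2, size=n_lines)
        switch = rng.random((n_lines, n_markers - 1)) < r[None, :]
        # cumulative XOR of switches gives the chain state at each marker
        calls = np.empty((n_lines, n_markers), dtype=np.int8)
        calls[:, 0] = first
        calls[:, 1:] = (first[:, None] + np.cumsum(switch, axis=1)) % 2
        blocks.append(calls)
        for j, p in enumerate(pos, start=1):
            marker_rows.append((f"m{chrom_idx:02d}_{j:03d}", chrom_idx, float(p)))

    calls = np.concatenate(blocks, axis=1)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = calls.copy()
        calls[mask] = MISSING

    markers = pd.DataFrame(marker_rows, columns=["marker_id", "chromosome", "position_cM"])
    line_ids = [f"{line_prefix}{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(line_ids=line_ids, markers=markers, calls=calls)


def build_design(
    water_levels: tuple[float, ...] = DEFAULT_WATER_LEVELS,
    nitrogen_levels: tuple[float, ...] = DEFAULT_NITROGEN_LEVELS,
    combos: list[tuple[float, float, int]] | None = None,
    reps: tuple[int, int] = (4, 8),
) -> StressDesign:
    """Build the face-centered two-stress design.

    The default nine combinations are the four extreme corners (min/max
    water x min/max nitrogen) and four intermediate "face" points (second/
    fourth levels paired with the middle level) at the corner replicate
    count, plus the center point at the (larger) center count. Degenerate
    single-level factors collapse to the center point alone. Explicit
    ``combos`` override the default and are validated against the levels.
    """
    w = tuple(sorted(float(x) for x in water_levels))
    n = tuple(sorted(float(x) for x in nitrogen_levels))
    if combos is not None:
        return StressDesign(combinations=tuple(
            (float(cw), float(cn), int(cr)) for cw, cn, cr in combos
        ), water_levels=w, nitrogen_levels=n)

    corner_reps, center_reps = reps
    wc, nc = w[len(w) // 2], n[len(n) // 2]
    if len(w) == 1 and len(n) == 1:
        combinations = [(w[0], n[0], center_reps)]
    else:
        combinations = [
            (w[0], n[0], corner_reps), (w[0], n[-1], corner_reps),
            (w[-1], n[0], corner_reps), (w[-1], n[-1], corner_reps),
        ]
        if len(w) >= 5 and len(n) >= 5:
            combinations += [
                (w[1], nc, corner_reps), (w[3], nc, corner_reps),
                (wc, n[1], corner_reps), (wc, n[3], corner_reps),
            ]
        combinations.append((wc, nc, center_reps))
    return StressDesign(combinations=tuple(combinations), water_levels=w,
                        nitrogen_levels=n)


def compute_kinship(genotypes: GenotypeMatrix, ridge: float = 0.0) -> KinshipMatrix:
    """Identity-in-state (allele-sharing) kinship.

    Pairwise proportion of markers, non-missing in both lines, at which the
    two lines carry the same allele; the diagonal is 1. A pair with no
    shared non-missing marker raises :class:`MissingDataError`. The mean
    diagonal is 1 by construction, so no rescaling is needed.
    """
    if genotypes.n_lines < 2:
        raise InvalidArgumentError("need >= 2 lines for kinship")
    calls = genotypes.calls
    observed = (calls != MISSING).astype(float)
    # same-allele indicator via products on the +/-1 coding, masked by presence
    signed = np.where(calls == MISSING, 0.0, np.where(calls == B73, 1.0, -1.0))
    shared = observed @ observed.T
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise MissingDataError(
            f"lines {genotypes.line_ids[i]!r} and {genotypes.line_ids[j]!r} "
            "share no non-missing markers"
        )
    agree = 0.5 * (signed @ signed.T + shared)
    K = agree / shared
    np.fill_diagonal(K, 1.0)
    # pairwise-complete estimates can be indefinite under missing data:
    # project onto the PSD cone and rescale the mean diagonal back to 1
    w, U = np.linalg.eigh(K)
    if w.min() < 0:
        K = (U * np.clip(w, 0.0, None)) @ U.T
        K = 0.5 * (K + K.T)
        K /= np.mean(np.diag(K))
    if ridge:
        K = K + ridge * np.eye(genotypes.n_lines)
    return KinshipMatrix(line_ids=list(genotypes.line_ids), values=K)


def validate_phenotypes(df: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check the phenotype-table contract and attach recentred covariates."""
    from .exceptions import FormatError

    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table missing columns {missing}")
    resid = (
        df["diff_height_cm"] - (df["final_height_cm"] - df["initial_height_cm"])
    ).abs()
    bad = np.flatnonzero(resid.to_numpy() > atol)
    if bad.size:
        raise FormatError(
            f"row {int(bad[0])}: diff_height_cm != final - initial "
            f"(|residual| = {resid.iloc[int(bad[0])]:.3g})"
        )
    out = df.copy()
    out["xw"] = recenter_water(df["water_pct"])
    out["xn"] = recenter_nitrogen(df["nitrogen_pct"])
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    design: StressDesign,
    causal_spec: dict[str, tuple[ProducingFunctionParams, ProducingFunctionParams]] | None = None,
    baseline: float = 30.0,
    sigma_line: float = 2.0,
    sigma_resid: float = 3.0,
    kinship: KinshipMatrix | None = None,
    seed: int = 0,
    initial_mu: float = 15.0,
    initial_sd: float = 2.0,
) -> pd.DataFrame:
    """Simulate growth records for every line x design replicate.

    ``causal_spec`` maps marker ids to a (B73-allele params, Mo17-allele
    params) pair of producing functions; lines with a missing call at a
    causal marker receive a random allele's effect there. Line effects are
    one draw from N(0, sigma_line^2 * K); defaults emulate the study's
    scale (baseline growth ~30 cm, line SD 2 cm, residual SD 3 cm, initial
    height N(15, 2^2) cm). Returns a validated phenotype DataFrame with
    recentred ``xw``/``xn`` columns attached.
    """
    if sigma_line < 0 or sigma_resid < 0 or initial_sd < 0:
        raise InvalidArgumentError("variance components must be >= 0")
    causal_spec = causal_spec or {}
    for marker_id in causal_spec:
        if marker_id not in set(genotypes.markers["marker_id"]):
            raise InvalidArgumentError(f"causal marker {marker_id!r} not in genotypes")

    rng = np.random.default_rng(seed)
    L = genotypes.n_lines

    if kinship is None:
        kinship = KinshipMatrix.identity(genotypes.line_ids)
    if list(kinship.line_ids) != list(genotypes.line_ids):
        raise InvalidArgumentError("kinship and genotype line_ids differ")
    K = kinship.values
    eigvals = np.linalg.eigvalsh(K)
    if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
        raise ModelSpecificationError("kinship matrix is not positive semi-definite")

    if sigma_line > 0:
        w, U = np.linalg.eigh(K)
        root = U * np.sqrt(np.clip(w, 0.0, None))
        alpha = sigma_line * (root @ rng.standard_normal(L))
    else:
        alpha = np.zeros(L)

    # one record per line x combination x replicate, in a fixed order;
    # the rng then permutes records within combinations (randomized layout)
    rows: list[tuple[str, float, float]] = []
    for water, nitrogen, nrep in design.combinations:
        cell_lines = [lid for lid in genotypes.line_ids for _ in range(nrep)]
        rng.shuffle(cell_lines)
        rows.extend((lid, water, nitrogen) for lid in cell_lines)

    df = pd.DataFrame(rows, columns=["line_id", "water_pct", "nitrogen_pct"])
    xw = recenter_water(df["water_pct"].to_numpy())
    xn = recenter_nitrogen(df["nitrogen_pct"].to_numpy())
    line_index = {lid: i for i, lid in enumerate(genotypes.line_ids)}
    li = df["line_id"].map(line_index).to_numpy()

    genetic = np.zeros(len(df))
    for marker_id, (params_b73, params_mo17) in causal_spec.items():
        calls = genotypes.marker_calls(marker_id).copy()
        miss = calls == MISSING
        if miss.any():
            calls[miss] = rng.integers(0, 2, size=int(miss.sum()))
        z_b73 = evaluate_producing(params_b73, xw, xn)
        z_mo17 = evaluate_producing(params_mo17, xw, xn)
        genetic += np.where(calls[li] == B73, z_b73, z_mo17)

    diff = baseline + genetic + alpha[li] + sigma_resid * rng.standard_normal(len(df))
    initial = initial_mu + initial_sd * rng.standard_normal(len(df))
    df["initial_height_cm"] = initial
    df["final_height_cm"] = initial + diff
    df["diff_height_cm"] = diff
    return validate_phenotypes(df)
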