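"""Simulate the study population: genotypes, kinship, design, phenotypes.

Generates 89 recombinant inbred lines over 10 chromosomes (200 markers),
computes allele-sharing kinship, and simulates growth under the nine-
combination two-stress design with one planted QTL whose alleles carry
the reference domed (B73-like) vs shallow-trough (Mo17-like) producing
functions. Writes the data files under results/simulated/.
"""

import sys
from pathlib import Path

import numpy as np

from surfaceqtl import io as sio
from surfaceqtl.synthetic import (
    build_design,
    compute_kinship,
    simulate_genotypes,
    simulate_phenotypes,
)
from surfaceqtl.tables import EXAMPLE_DOMED_PARAMS, EXAMPLE_TROUGH_PARAMS

RESULTS = Path(__file__).resolve().parents[1] / "results" / "simulated"
CAUSAL_MARKER = "m05_010"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(89, seed=seed)
    kinship = compute_kinship(genotypes)
    design = build_design()
    phenotypes = simulate_phenotypes(
        genotypes, design,
        causal_spec={CAUSAL_MARKER: (EXAMPLE_DOMED_PARAMS, EXAMPLE_TROUGH_PARAMS)},
        sigma_line=2.0, sigma_resid=3.0, kinship=kinship, seed=seed + 1,
    )
    sio.write_genotypes(genotypes, RESULTS / "genotypes.csv", RESULTS / "marker_map.csv")
    sio.write_kinship(kinship, RESULTS / "kinship.csv")
    sio.write_phenotypes(phenotypes, RESULTS / "phenotypes.csv")
    offdiag = kinship.values[~np.eye(len(kinship.line_ids), dtype=bool)]
    print(f"{genotypes.n_lines} lines x {genotypes.n_markers} markers; "
          f"{len(phenotypes)} phenotype records over {len(design.combinations)} "
          f"stress combinations")
    print(f"kinship off-diagonal mean {offdiag.mean():.3f} "
          f"(range {offdiag.min():.3f}-{offdiag.max():.3f})")
    print(f"planted QTL at {CAUSAL_MARKER}; wrote data under {RESULTS}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
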