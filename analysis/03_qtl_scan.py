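"""Scan the simulated population for response-surface QTL.

Reads the files written by 02_simulate_population.py, runs the kinship-
weighted F-test scan, smooths p-values with a 5-marker Simes window, and
calls QTL intervals under both the Sidak 0.05 experiment-wise threshold
and the 0.05 FDR. Writes results/scan.tsv, the interval tables and a
Manhattan-style figure.
"""

from pathlib import Path

from surfaceqtl import io as sio
from surfaceqtl.plotting import scan_manhattan
from surfaceqtl.scan import call_qtl, marker_scan, simes_smooth

RESULTS = Path(__file__).resolve().parents[1] / "results"
DATA = RESULTS / "simulated"


def main() -> None:
    phenotypes = sio.read_phenotypes(DATA / "phenotypes.csv")
    genotypes = sio.read_genotypes(DATA / "genotypes.csv", DATA / "marker_map.csv")
    kinship = sio.read_kinship(DATA / "kinship.csv")
    scan = marker_scan(phenotypes, genotypes, kinship)
    simes_smooth(scan, window=5)
    vc = scan.variance_components
    print(f"REML variance components: sigma_line^2={vc.sigma_line2:.2f}, "
          f"sigma_resid^2={vc.sigma_resid2:.2f}")
    for method in ("sidak", "fdr"):
        intervals = call_qtl(scan, criterion=method, alpha=0.05)
        sio.write_intervals(intervals, RESULTS / f"qtl_intervals_{method}.tsv")
        print(f"{method}: {len(intervals)} interval(s): "
              + "; ".join(f"chr{iv.chromosome} {iv.start_marker}..{iv.end_marker} "
                          f"(best {iv.best_marker}, p={iv.best_p:.2e})"
                          for iv in intervals))
    sio.write_scan(scan, RESULTS / "scan.tsv")
    scan_manhattan(scan.markers.dropna(subset=["smoothed_p"]), RESULTS / "scan.png",
                   alpha_line=0.05)
    print(f"wrote {RESULTS/'scan.tsv'}")


if __name__ == "__main__":
    main()
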