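#!/usr/bin/env python
"""Simulate the emulated study population and write its input files.

A biparental maize RIL panel: 145 lines, 10 chromosomes, 292 markers over
1787.5 cM, phenotyped for 7 correlated traits (root morphology, biomass and
P content roles) in 4 randomized complete blocks. Four QTLs of 0.25-0.40
progeny-sd are planted (chromosomes 1, 3, 4 and 8), with one epistatic
interaction between the first two; 2% of marker calls are blanked.

Writes map.tsv, genotypes.csv, phenotypes.csv and truth.json under
results/study/.
"""

from pathlib import Path

import numpy as np

from rilqtl import io, simdata

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 20260901

TRAITS, SIGMA = simdata.table1_like_correlation()
QTLS = [("1", 62.0), ("3", 105.0), ("4", 31.0), ("8", 140.0)]
BETA = np.zeros((4, 7))
BETA[0, [0, 1, 5]] = [0.35, 0.30, 0.28]        # SA, RL, TDW
BETA[1, [2, 6]] = [0.32, 0.27]                 # SA2, Pcont
BETA[2, [3]] = [-0.40]                         # RD (allele from parent B)
BETA[3, [5, 6]] = [0.26, 0.33]                 # TDW, Pcont
EPISTASIS = [((0, 1), np.array([0.0, 0.25, 0.0, 0.0, 0.0, 0.3, 0.0]))]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gmap = simdata.paper_like_map()
    geno, codes = simdata.simulate_ril_genotypes(gmap, QTLS, 145, seed=SEED)
    geno = simdata.inject_missing(geno, 0.02, seed=SEED + 1)
    arch = simdata.SimArchitecture(
        qtl_loci=QTLS,
        additive_effects=BETA,
        # 4x the line-level covariance: replicate averaging over 4 blocks
        # leaves line-mean residuals with unit-diagonal covariance, so the
        # planted effects are in progeny-sd units
        residual_covariance=4.0 * SIGMA,
        trait_names=TRAITS,
        epistatic_terms=EPISTASIS,
        n_replicates=4,
        seed=SEED + 2,
    )
    records = simdata.simulate_phenotypes(codes, arch)
    io.write_map(gmap, OUT / "map.tsv")
    io.write_genotypes(geno, OUT / "genotypes.csv")
    io.write_phenotypes(records, OUT / "phenotypes.csv")
    io.write_truth_json(OUT / "truth.json", QTLS, BETA, EPISTASIS, TRAITS)
    print(f"study written to {OUT}")
    print(f"  {gmap.n_markers} markers, {len(geno.lines)} lines, "
          f"{len(TRAITS)} traits, {len(QTLS)} QTLs + "
          f"{len(EPISTASIS)} epistatic pair(s)")


if __name__ == "__main__":
    main()
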