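"""Shared fixtures: small simulated maps, populations and phenotypes.

Everything is generated at test time with fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

from rilqtl import genmap, simdata


@pytest.fixture(scope="session")
def small_map() -> genmap.GeneticMap:
    """Two chromosomes, markers every 10 cM over 0-50 cM."""
    return simdata.simulate_map(2, 50.0, 6, spacing="uniform", seed=0)


@pytest.fixture(scope="session")
def small_population(small_map):
    """145 RILs with one planted QTL per chromosome."""
    qtls = [("1", 25.0), ("2", 12.0)]
    geno, codes = simdata.simulate_ril_genotypes(
        small_map, qtls, 145, seed=11
    )
    return qtls, geno, codes


@pytest.fixture(scope="session")
def small_probs(small_map, small_population):
    _, geno, _ = small_population
    return genmap.qtl_genotype_probabilities(small_map, geno, step=1.0)


@pytest.fixture(scope="session")
def two_trait_study(small_map, small_population):
    """Phenotypes for two traits driven by the two planted QTLs."""
    qtls, geno, codes = small_population
    arch = simdata.SimArchitecture(
        qtl_loci=qtls,
        additive_effects=np.array([[0.5, 0.1], [0.0, 0.45]]),
        residual_covariance=np.array([[1.0, 0.3], [0.3, 1.0]]),
        trait_names=["TA", "TB"],
        n_replicates=4,
        seed=23,
    )
    records = simdata.simulate_phenotypes(codes, arch)
    return arch, records


@pytest.fixture(scope="session")
def balanced_records():
    """Small balanced RCBD data with known parameters, zero noise."""
    lines = [f"L{j}" for j in range(6)]
    blocks = ["B1", "B2", "B3"]
    G = np.array([0.5, -0.2, 0.0, 0.8, -0.6, -0.5])
    B = np.array([0.3, -0.1, -0.2])
    rows = [
        (ln, bk, "trait", 10.0 + B[b] + G[j])
        for j, ln in enumerate(lines)
        for b, bk in enumerate(blocks)
    ]
    return pd.DataFrame(rows, columns=["line", "block", "trait", "value"])
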