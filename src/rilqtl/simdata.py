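"""Synthetic selfed-RIL populations with multi-trait QTL architectures.

Emulates the study design the inference modules assume: a biparental maize
RIL panel (default 145 lines) genotyped on a 10-chromosome map of ~292
markers spanning 1787.5 cM, phenotyped for up to 7 correlated traits in a
randomized complete block design with 4 replicates. Genomes are drawn from
the same two-state Markov chain (per-interval switch probability = collapsed
RIL recombination fraction) that the genotype-probability machinery assumes,
so simulation and inference share one generative model.

Phenotypes follow the multi-trait multiple-interval-mapping equation:
    y_itb = mu_t + block_tb + sum_r beta_tr x_ir + sum_(r<l) w_trl x_ir x_il + e_it
with per-line trait-vector residuals drawn from MVN(0, Sigma_eps), optionally
scaled per line (heteroscedasticity) and with optional missing marker calls.
All randomness flows through explicit integer seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import (
    GeneticMap,
    MarkerGenotypes,
    kosambi_to_recfrac,
    ril_collapse,
)

__all__ = [
    "SimArchitecture",
    "simulate_map",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "inject_missing",
    "paper_like_map",
    "table1_like_correlation",
]

# Default block shifts (phenotype-sd units) across the 4 replicates.
DEFAULT_BLOCK_EFFECTS = (-0.3, -0.1, 0.1, 0.3)


@dataclass
class SimArchitecture:
    """Trait architecture for :func:`simulate_phenotypes`.

    Effects are in phenotype-standard-deviation units; with the +/-1 genotype
    coding a QTL with additive effect beta explains roughly beta^2 of the
    variance of a unit-variance trait.
    """

    qtl_loci: list[tuple[str, float]]          # (chrom, pos cM)
    additive_effects: np.ndarray               # (n_qtl, n_traits)
    residual_covariance: np.ndarray            # (n_traits, n_traits), PD
    trait_names: list[str]
    epistatic_terms: list[tuple[tuple[int, int], np.ndarray]] = field(
        default_factory=list
    )                                          # ((r, l), per-trait effects)
    trait_means: np.ndarray | None = None
    block_effects: np.ndarray | None = None    # (n_reps, n_traits)
    n_replicates: int = 4
    heteroscedastic_sd_multipliers: np.ndarray | None = None  # per line
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.additive_effects = np.atleast_2d(
            np.asarray(self.additive_effects, dtype=float)
        )
        S = np.asarray(self.residual_covariance, dtype=float)
        if not np.allclose(S, S.T):
            raise ValueError("residual covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError("residual covariance must be positive definite")
        self.residual_covariance = S
        T = S.shape[0]
        if self.additive_effects.shape != (len(self.qtl_loci), T):
            raise ValueError("additive_effects must be (n_qtl, n_traits)")
        if len(self.trait_names) != T:
            raise ValueError("trait_names length mismatch")
        if self.trait_means is None:
            self.trait_means = np.zeros(T)
        if self.block_effects is None:
            base = np.asarray(DEFAULT_BLOCK_EFFECTS[: self.n_replicates])
            if len(base) < self.n_replicates:
                base = np.linspace(-0.3, 0.3, self.n_replicates)
            self.block_effects = np.repeat(base[:, None], T, axis=1)
        self.block_effects = np.asarray(self.block_effects, dtype=float)
        if self.block_effects.shape != (self.n_replicates, T):
            raise ValueError("block_effects must be (n_replicates, n_traits)")
        for (r, l), w in self.epistatic_terms:
            if not (0 <= r < len(self.qtl_loci) and 0 <= l < len(self.qtl_loci)):
                raise ValueError("epistatic term references an unknown QTL")
            if np.asarray(w).shape != (T,):
                raise ValueError("epistatic effects must be per-trait vectors")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_traits(self) -> int:
        return self.residual_covariance.shape[0]


def simulate_map(
    n_chrom: int,
    chrom_lengths_cM,
    markers_per_chrom,
    spacing: str = "uniform",
    seed: int = 0,
) -> GeneticMap:
    """Simulate a linkage map; marker names are ``m<chrom>_<index>``."""
    lengths = np.broadcast_to(
        np.asarray(chrom_lengths_cM, dtype=float), (n_chrom,)
    )
    n_mark = np.broadcast_to(np.asarray(markers_per_chrom, dtype=int), (n_chrom,))
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    if np.any(n_mark < 2):
        raise ValueError("need at least 2 markers per chromosome")
    rng = np.random.default_rng(seed)
    chroms = [str(c + 1) for c in range(n_chrom)]
    markers, positions = {}, {}
    for c, (L, M) in enumerate(zip(lengths, n_mark)):
        if spacing == "uniform":
            pos = np.linspace(0.0, L, M)
        elif spacing == "random":
            interior = np.sort(rng.uniform(0.0, L, size=M - 2))
            pos = np.concatenate([[0.0], interior, [L]])
        else:
            raise ValueError("spacing must be 'uniform' or 'random'")
        markers[chroms[c]] = [f"m{chroms[c]}_{j + 1}" for j in range(M)]
        positions[chroms[c]] = pos
    return GeneticMap(chroms, markers, positions)


def paper_like_map(seed: int = 0) -> GeneticMap:
    """The emulated study map: 10 chromosomes, 292 markers, 1787.5 cM total."""
    per_chrom = [30] * 2 + [29] * 8  # 292 markers
    return simulate_map(10, 178.75, per_chrom, spacing="uniform", seed=seed)


def _merged_loci(gmap: GeneticMap, extra_loci):
    """Per chromosome: sorted positions of markers + QTL pseudo-loci."""
    merged = {}
    for c in gmap.chromosomes:
        qtl = [(p, k) for k, (cc, p) in enumerate(extra_loci) if cc == c]
        lo, hi = gmap.chrom_extent(c)
        for p, _ in qtl:
            if not (lo <= p <= hi):
                raise ValueError(f"QTL position {c}:{p} outside map extent")
        entries = [(p, ("M", j)) for j, p in enumerate(gmap.positions[c])]
        entries += [(p, ("Q", k)) for p, k in qtl]
        entries.sort(key=lambda t: (t[0], t[1][0] == "Q"))
        merged[c] = entries
    known = {c for c in gmap.chromosomes}
    for cc, _ in extra_loci:
        if cc not in known:
            raise ValueError(f"QTL chromosome {cc} not on the map")
    return merged


def simulate_ril_genotypes(
    gmap: GeneticMap,
    extra_loci,
    n_lines: int,
    seed: int = 0,
) -> tuple[MarkerGenotypes, np.ndarray]:
    """Draw RIL genomes as a two-state chain over markers + QTL pseudo-loci.

    The first locus of each chromosome is +/-1 with probability 1/2; each
    subsequent locus flips with the collapsed RIL recombination fraction of
    the interval. Returns the marker matrix and a separate (n_lines, n_qtl)
    matrix of true QTL codes (never written into marker output).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    merged = _merged_loci(gmap, extra_loci)
    marker_cols: dict[int, np.ndarray] = {}
    qtl_cols = np.empty((n_lines, len(extra_loci)))
    col_offset = 0
    marker_mat = np.empty((n_lines, gmap.n_markers))
    for c in gmap.chromosomes:
        entries = merged[c]
        pos = np.array([p for p, _ in entries])
        d = np.diff(pos)
        R = ril_collapse(kosambi_to_recfrac(d))
        states = np.empty((n_lines, len(entries)))
        states[:, 0] = rng.choice([-1.0, 1.0], size=n_lines)
        flips = rng.random((n_lines, len(d))) < R[None, :]
        signs = np.where(flips, -1.0, 1.0)
        states[:, 1:] = states[:, [0]] * np.cumprod(signs, axis=1)
        for k, (p, (kind, idx)) in enumerate(entries):
            if kind == "M":
                marker_mat[:, col_offset + idx] = states[:, k]
            else:
                qtl_cols[:, idx] = states[:, k]
        col_offset += len(gmap.markers[c])
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return (
        MarkerGenotypes(lines, gmap.marker_names, marker_mat),
        qtl_cols,
    )


def simulate_phenotypes(
    true_qtl_codes: np.ndarray, arch: SimArchitecture
) -> pd.DataFrame:
    """Phenotype records (long format: line, block, trait, value).

    For line j, trait t, replicate b:
    y = mu_t + block_tb + sum_r beta_tr x_jr + sum w_trl x_jr x_jl + eps,
    with eps ~ MVN(0, Sigma_eps) per (line, replicate), optionally scaled by
    a per-line sd multiplier.
    """
    X = np.atleast_2d(np.asarray(true_qtl_codes, dtype=float))
    n_lines, n_qtl = X.shape
    if n_qtl != len(arch.qtl_loci):
        raise ValueError("true_qtl_codes columns must match arch.qtl_loci")
    T = arch.n_traits
    genetic = X @ arch.additive_effects  # (n_lines, T)
    for (r, l), w in arch.epistatic_terms:
        genetic += np.outer(X[:, r] * X[:, l], np.asarray(w, dtype=float))
    rng = np.random.default_rng(arch.seed)
    L = np.linalg.cholesky(arch.residual_covariance)
    mult = (
        np.ones(n_lines)
        if arch.heteroscedastic_sd_multipliers is None
        else np.asarray(arch.heteroscedastic_sd_multipliers, dtype=float)
    )
    if mult.shape != (n_lines,) or np.any(mult <= 0):
        raise ValueError("sd multipliers must be positive, one per line")
    records = []
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    for b in range(arch.n_replicates):
        eps = rng.standard_normal((n_lines, T)) @ L.T
        y = (
            arch.trait_means[None, :]
            + arch.block_effects[b][None, :]
            + genetic
            + eps * mult[:, None]
        )
        for i in range(n_lines):
            for t in range(T):
                records.append(
                    (lines[i], f"B{b + 1}", arch.trait_names[t], y[i, t])
                )
    return pd.DataFrame(records, columns=["line", "block", "trait", "value"])


def inject_missing(
    geno: MarkerGenotypes, rate: float, seed: int = 0
) -> MarkerGenotypes:
    """Independently blank each observed call with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = geno.codes.copy()
    mask = rng.random(codes.shape) < rate
    codes[mask] = np.nan
    return MarkerGenotypes(list(geno.lines), list(geno.marker_names), codes)


def table1_like_correlation() -> tuple[list[str], np.ndarray]:
    """A 7-trait correlation structure resembling the study's trait panel.

    Traits: root surface area (SA), root length (RL), surface area of fine
    roots (SA2), root diameter (RD), root:shoot ratio (RS), total seedling
    dry weight (TDW), total P content (Pcont). The printed 2-dp matrix is
    slightly indefinite, so a small eigenvalue floor is applied and the
    result rescaled back to unit diagonal.
    """
    names = ["SA", "RL", "SA2", "RD", "RS", "TDW", "Pcont"]
    C = np.array(
        [
            [1.00, 0.98, 0.80, -0.48, -0.38, 0.86, 0.39],
            [0.98, 1.00, 0.69, -0.62, -0.38, 0.79, 0.31],
            [0.80, 0.69, 1.00, 0.03, -0.29, 0.77, 0.48],
            [-0.48, -0.62, 0.03, 1.00, 0.26, -0.25, 0.14],
            [-0.38, -0.38, -0.29, 0.26, 1.00, -0.43, -0.02],
            [0.86, 0.79, 0.77, -0.25, -0.43, 1.00, 0.58],
            [0.39, 0.31, 0.48, 0.14, -0.02, 0.58, 1.00],
        ]
    )
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, 1e-3)
    C = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    return names, (C + C.T) / 2.0
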