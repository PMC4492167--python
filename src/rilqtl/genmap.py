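"""Genetic map, map-function conversions, and RIL genotype probabilities.

The mapping population is a biparental recombinant-inbred-line (RIL) panel:
each line is (near-)fully homozygous, so marker genotypes take two parental
codes, +1 (parent A, the trait-donor role) and -1 (parent B). Distances are
genetic (centiMorgan) under the Kosambi map function; meiotic recombination
fractions are collapsed to RIL recombination fractions with the
Haldane-Waddington infinite-selfing limit R = 2r/(1+2r).

Multilocus RIL genotypes are modelled as a two-state Markov chain along each
chromosome whose per-interval switch probability is the collapsed RIL
recombination fraction of that interval. Conditional QTL genotype
probabilities on a cM grid condition on the nearest informative (non-missing)
flanking marker on each side, which for a Markov chain equals the full
forward-backward result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = np.nan

__all__ = [
    "GeneticMap",
    "MarkerGenotypes",
    "GenotypeProbabilities",
    "SegregationTestResult",
    "kosambi_to_recfrac",
    "recfrac_to_kosambi",
    "ril_collapse",
    "qtl_genotype_probabilities",
    "segregation_test",
]

_TIE_JITTER = 1e-6  # cM added to co-located markers, in file order


def kosambi_to_recfrac(d):
    """Convert Kosambi map distance (cM) to meiotic recombination fraction.

    r = 0.5 * tanh(2 d / 100). Strictly increasing, r < 0.5.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(0.02 * d)
    return float(r) if r.ndim == 0 else r


def recfrac_to_kosambi(r):
    """Convert meiotic recombination fraction to Kosambi map distance (cM).

    d = 25 * ln((1+2r)/(1-2r)); exact inverse of :func:`kosambi_to_recfrac`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def ril_collapse(r):
    """Collapse a meiotic recombination fraction to its selfed-RIL value.

    Haldane-Waddington infinite-selfing limit R = 2r/(1+2r). Residual
    heterozygosity after a finite number of selfing generations is ignored:
    the genotype code space has only the two homozygous classes.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


@dataclass
class GeneticMap:
    """Ordered marker positions (cM) per chromosome.

    ``positions[c]`` is strictly increasing; co-located markers are jittered
    by +1e-6 cM in input order. Marker names are unique genome-wide.
    """

    chromosomes: list[str]
    markers: dict[str, list[str]]     # chrom -> marker names, map order
    positions: dict[str, np.ndarray]  # chrom -> cM positions, float

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.chromosomes:
            pos = np.asarray(self.positions[c], dtype=float)
            if np.any(pos < 0):
                raise ValueError(f"negative cM position on chromosome {c}")
            if len(pos) != len(self.markers[c]):
                raise ValueError(f"marker/position length mismatch on {c}")
            # jitter exact ties in order, then demand strict increase
            for i in range(1, len(pos)):
                if pos[i] <= pos[i - 1]:
                    if np.isclose(pos[i], pos[i - 1], atol=1e-9):
                        pos[i] = pos[i - 1] + _TIE_JITTER
                        logger.info(
                            "co-located marker %s on %s jittered by %g cM",
                            self.markers[c][i], c, _TIE_JITTER,
                        )
                    else:
                        raise ValueError(
                            f"positions not increasing on chromosome {c} "
                            f"at marker {self.markers[c][i]}"
                        )
            self.positions[c] = pos
            for m in self.markers[c]:
                if m in seen:
                    raise ValueError(f"duplicate marker name {m}")
                seen.add(m)

    @property
    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in self.markers[c]]

    @property
    def n_markers(self) -> int:
        return sum(len(self.markers[c]) for c in self.chromosomes)

    def chrom_extent(self, chrom: str) -> tuple[float, float]:
        pos = self.positions[chrom]
        return float(pos[0]), float(pos[-1])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, c, p)
            for c in self.chromosomes
            for m, p in zip(self.markers[c], self.positions[c])
        ]
        return pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        chroms = list(dict.fromkeys(df["chrom"].astype(str)))
        markers, positions = {}, {}
        for c in chroms:
            sub = df[df["chrom"].astype(str) == c].sort_values(
                "pos_cM", kind="stable"
            )
            markers[c] = sub["marker"].astype(str).tolist()
            positions[c] = sub["pos_cM"].to_numpy(dtype=float)
        return cls(chroms, markers, positions)


@dataclass
class MarkerGenotypes:
    """Line x marker genotype codes in {+1, -1, NaN=missing}."""

    lines: list[str]
    marker_names: list[str]
    codes: np.ndarray  # (n_lines, n_markers) float

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.lines), len(self.marker_names)):
            raise ValueError("genotype matrix shape mismatch")
        obs = self.codes[~np.isnan(self.codes)]
        if not np.all(np.isin(obs, (-1.0, 1.0))):
            raise ValueError("genotype codes must be +1, -1 or missing")

    def column(self, marker: str) -> np.ndarray:
        return self.codes[:, self.marker_names.index(marker)]


@dataclass
class GenotypeProbabilities:
    """Conditional P(genotype = +1 | marker data) on a cM scan grid.

    ``q`` has one row per line and one column per grid position; the derived
    expected Cockerham code is ``xhat = 2 q - 1``. At a grid position that
    coincides with an observed marker, xhat equals the observed code exactly.
    """

    lines: list[str]
    grid: pd.DataFrame  # columns chrom, pos_cM; row order = q columns
    q: np.ndarray       # (n_lines, n_grid) in [0, 1]

    @property
    def xhat(self) -> np.ndarray:
        return 2.0 * self.q - 1.0

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.grid["chrom"] == chrom).to_numpy()

    def position_index(self, chrom: str, pos: float) -> int:
        mask = self.chrom_mask(chrom)
        idx = np.flatnonzero(mask & np.isclose(self.grid["pos_cM"], pos))
        if len(idx) == 0:
            raise KeyError(f"position {chrom}:{pos} not on the scan grid")
        return int(idx[0])


def _chrom_grid(pos: np.ndarray, step: float) -> np.ndarray:
    """Union of marker positions and step-spaced points across the chromosome."""
    lo, hi = pos[0], pos[-1]
    stepped = np.arange(lo, hi, step) if hi > lo else np.array([lo])
    # exact marker positions must survive the union untouched so that
    # marker-coincident grid points condition at distance exactly zero
    return np.union1d(stepped, pos)


def _condition_line(obs_pos, obs_code, grid):
    """q at each grid point given nearest informative flanks (one line)."""
    q = np.full(grid.shape, 0.5)
    if obs_pos.size == 0:
        return q
    # index of nearest informative marker at-or-left / at-or-right
    right_idx = np.searchsorted(obs_pos, grid, side="left")
    left_idx = np.searchsorted(obs_pos, grid, side="right") - 1
    has_left = left_idx >= 0
    has_right = right_idx < obs_pos.size

    d_left = np.where(has_left, grid - obs_pos[np.clip(left_idx, 0, None)], 0.0)
    d_right = np.where(
        has_right, obs_pos[np.clip(right_idx, None, obs_pos.size - 1)] - grid, 0.0
    )
    R_left = ril_collapse(kosambi_to_recfrac(d_left))
    R_right = ril_collapse(kosambi_to_recfrac(d_right))
    g_left = obs_code[np.clip(left_idx, 0, None)]
    g_right = obs_code[np.clip(right_idx, None, obs_pos.size - 1)]

    # P(state=+1 | left flank), P(right flank | state=+1) and complements
    a = np.where(g_left > 0, 1.0 - R_left, R_left)          # P(+1 | gL)
    b = np.where(g_right > 0, 1.0 - R_right, R_right)       # P(gR | +1)
    a_c = 1.0 - a                                           # P(-1 | gL)
    b_c = np.where(g_right > 0, R_right, 1.0 - R_right)     # P(gR | -1)

    both = has_left & has_right
    only_l = has_left & ~has_right
    only_r = ~has_left & has_right
    q[both] = (a * b)[both] / (a * b + a_c * b_c)[both]
    q[only_l] = a[only_l]
    # by reversibility of the stationary two-state chain P(+1 | gR) = b / (b+b_c)
    q[only_r] = b[only_r]
    return q


def qtl_genotype_probabilities(
    gmap: GeneticMap, geno: MarkerGenotypes, step: float = 1.0
) -> GenotypeProbabilities:
    """Conditional +1-genotype probabilities for every line on a cM grid.

    The grid is the union of all marker positions and ``step``-spaced points
    between the first and last marker of each chromosome, anchored at the
    first marker (no re-zeroing). Conditioning uses the nearest informative
    marker per side under the two-state RIL chain; a line with no genotyped
    marker on a chromosome gets q = 0.5 across it (with a warning).
    """
    if geno.marker_names != gmap.marker_names:
        raise ValueError("genotype columns do not match the map's markers")
    grids, chrom_of = [], []
    col_of = {m: j for j, m in enumerate(gmap.marker_names)}
    blocks = []
    for c in gmap.chromosomes:
        pos = gmap.positions[c]
        grid = _chrom_grid(pos, step)
        grids.append(grid)
        chrom_of.extend([c] * len(grid))
        cols = [col_of[m] for m in gmap.markers[c]]
        obs_all = geno.codes[:, cols]
        block = np.empty((len(geno.lines), len(grid)))
        for i in range(len(geno.lines)):
            informative = ~np.isnan(obs_all[i])
            if not informative.any():
                logger.warning(
                    "line %s has no genotyped marker on chromosome %s; q=0.5",
                    geno.lines[i], c,
                )
            block[i] = _condition_line(
                pos[informative], obs_all[i, informative], grid
            )
        blocks.append(block)
    grid_df = pd.DataFrame(
        {"chrom": chrom_of, "pos_cM": np.concatenate(grids)}
    )
    return GenotypeProbabilities(
        lines=list(geno.lines), grid=grid_df, q=np.hstack(blocks)
    )


@dataclass
class SegregationTestResult:
    marker: str
    n_plus: int
    n_minus: int
    chi2: float
    p_value: float
    rejected: bool
    testable: bool = True


def segregation_test(
    geno: MarkerGenotypes, alpha: float = 0.05
) -> list[SegregationTestResult]:
    """Per-marker 1-df chi-square test of 1:1 segregation, Bonferroni-corrected.

    The rejection flag is true iff p < alpha / M where M is the number of
    testable markers (those with at least one non-missing call).
    """
    counts = []
    for j, m in enumerate(geno.marker_names):
        col = geno.codes[:, j]
        obs = col[~np.isnan(col)]
        counts.append((m, int((obs > 0).sum()), int((obs < 0).sum())))
    testable = [(m, p, q) for m, p, q in counts if p + q > 0]
    M = len(testable)
    results = []
    for m, np_, nm in counts:
        n = np_ + nm
        if n == 0:
            results.append(
                SegregationTestResult(m, 0, 0, np.nan, np.nan, False, False)
            )
            continue
        chi2 = (np_ - nm) ** 2 / n
        p = float(stats.chi2.sf(chi2, df=1))
        results.append(
            SegregationTestResult(m, np_, nm, float(chi2), p, p < alpha / M)
        )
    return results
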