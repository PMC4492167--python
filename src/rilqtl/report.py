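"""Map summaries, bin-based QTL naming, and report tables.

QTL report rows follow the field's table conventions for biparental QTL
studies: one row per QTL with its peak position, LOD, flanking markers from
the 1.5-LOD support interval, and per-trait additive effect (in progeny-sd
units, positive = parent-A allele increases the trait), significance stars
and R^2; epistatic rows join the two parent QTL names with " X ". When a
user-supplied bin table (the maize ~20 cM core-marker framework) is given,
QTLs are named ``q<Trait><bin>`` / ``qMulti<bin>``; otherwise the fallback
is ``q<Trait><chrom>@<cM>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .mimcore import EffectTest, QTLModel, ScanProfile, SupportInterval

logger = logging.getLogger(__name__)

__all__ = [
    "MapSummary", "BinTable", "map_summary", "generate_qtl_report",
    "export_scan_profiles",
]


@dataclass
class MapSummary:
    total_length_cM: float
    n_markers: int
    n_chromosomes: int
    mean_spacing_paper: float      # total / markers, rounded to 0.1 cM
    mean_spacing_intervals: float  # total / (markers - chromosomes)


def map_summary(gmap: GeneticMap) -> MapSummary:
    """Total map length and mean marker spacing under both conventions."""
    total = sum(
        gmap.positions[c][-1] - gmap.positions[c][0] for c in gmap.chromosomes
    )
    M = gmap.n_markers
    C = len(gmap.chromosomes)
    return MapSummary(
        total_length_cM=float(total),
        n_markers=M,
        n_chromosomes=C,
        mean_spacing_paper=float(round(total / M, 1)),
        mean_spacing_intervals=float(total / (M - C)),
    )


@dataclass
class BinTable:
    """User-supplied (bin label, chromosome, start cM, end cM) annotation."""

    records: pd.DataFrame  # columns: bin, chrom, start_cM, end_cM

    def __post_init__(self):
        need = {"bin", "chrom", "start_cM", "end_cM"}
        if not need <= set(self.records.columns):
            raise ValueError(f"bin table needs columns {sorted(need)}")
        for c, sub in self.records.groupby("chrom"):
            s = sub.sort_values("start_cM")
            if (s["end_cM"].to_numpy()[:-1] > s["start_cM"].to_numpy()[1:]
                    + 1e-9).any():
                raise ValueError(f"overlapping bins on chromosome {c}")

    def lookup(self, chrom: str, pos: float) -> str | None:
        sub = self.records[self.records["chrom"].astype(str) == str(chrom)]
        hit = sub[(sub["start_cM"] <= pos) & (pos <= sub["end_cM"])]
        return None if hit.empty else str(hit["bin"].iloc[0])


def _qtl_name(label, chrom, pos, bins: BinTable | None) -> str:
    if bins is not None:
        b = bins.lookup(chrom, pos)
        if b is not None:
            return f"q{label}{b}"
        logger.warning("QTL at %s:%.1f falls outside all bins; fallback name",
                       chrom, pos)
    return f"q{label}{chrom}@{pos:g}"


def generate_qtl_report(
    model: QTLModel,
    intervals: list[SupportInterval],
    per_effect_r2: dict,
    total_r2: pd.Series,
    tests: list[EffectTest],
    bin_table: BinTable | None = None,
    label: str = "Multi",
) -> pd.DataFrame:
    """One row per QTL term and per epistatic pair, report-table shaped.

    Columns: qtl, chrom, pos_cM, lod, flank_left, flank_right, then per
    trait ``effect_<t>``, ``stars_<t>``, ``r2_<t>``; the last row carries
    the per-trait total R^2 of the full model.
    """
    by_int = {iv.term_index: iv for iv in intervals}
    tmap: dict[tuple[str, int, str], EffectTest] = {
        (t.kind, t.index, t.trait): t for t in tests
    }
    names = [
        _qtl_name(label, c, p, bin_table) for c, p in model.terms
    ]
    rows = []
    for j, (c, p) in enumerate(model.terms):
        iv = by_int.get(j)
        row = {
            "qtl": names[j],
            "chrom": c,
            "pos_cM": p,
            "lod": iv.peak_lod if iv else np.nan,
            "flank_left": iv.left_marker if iv else None,
            "flank_right": iv.right_marker if iv else None,
        }
        for t in model.trait_names:
            et = tmap.get(("additive", j, t))
            row[f"effect_{t}"] = model.beta[j, model.trait_names.index(t)]
            row[f"stars_{t}"] = et.stars if et else ""
            row[f"r2_{t}"] = per_effect_r2[("additive", j)][t]
        rows.append(row)
    for k, (r, l) in enumerate(model.pairs):
        row = {
            "qtl": f"{names[r]} X {names[l]}",
            "chrom": "",
            "pos_cM": np.nan,
            "lod": np.nan,
            "flank_left": None,
            "flank_right": None,
        }
        for t in model.trait_names:
            et = tmap.get(("epistatic", k, t))
            row[f"effect_{t}"] = model.w[k, model.trait_names.index(t)]
            row[f"stars_{t}"] = et.stars if et else ""
            row[f"r2_{t}"] = per_effect_r2[("epistatic", k)][t]
        rows.append(row)
    total = {
        "qtl": "R2_T", "chrom": "", "pos_cM": np.nan, "lod": np.nan,
        "flank_left": None, "flank_right": None,
    }
    for t in model.trait_names:
        total[f"effect_{t}"] = np.nan
        total[f"stars_{t}"] = ""
        total[f"r2_{t}"] = total_r2[t]
    rows.append(total)
    return pd.DataFrame(rows)


def export_scan_profiles(
    profiles: dict[str, ScanProfile], outdir, plot: bool = False
) -> list[str]:
    """One TSV (chrom, pos_cM, lod, score) per profile; optional joint plot."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, prof in profiles.items():
        df = prof.grid.copy()
        df["lod"] = prof.lod
        df["score"] = prof.score
        p = outdir / f"scan_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(str(p))
    if plot and profiles:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3.5))
        for name, prof in profiles.items():
            x = np.arange(len(prof.lod))
            ax.plot(x, prof.lod, lw=1, label=name)
        ax.set_xlabel("grid index (genome order)")
        ax.set_ylabel("LOD")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = outdir / "scan_profiles.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    return written
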