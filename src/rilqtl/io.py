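"""Readers and writers for the pipeline's plain-text formats.

Formats: genetic map TSV (``marker  chrom  pos_cM``), genotype CSV (first
column ``line``, remaining columns marker names, cells in a configurable
code alphabet, default A/B/NA for the two parental homozygotes and missing),
phenotype CSV in long format (``line,block,trait,value``) with a wide-format
importer, trait-matrix CSV with a JSON sidecar, fitted-model JSON, scan TSV
and simulation truth JSON. All writers emit deterministic, byte-stable text.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap, MarkerGenotypes
from .mimcore import QTLModel
from .phenoprep import TraitMatrix

logger = logging.getLogger(__name__)

DEFAULT_CODE_MAP = {"A": 1.0, "B": -1.0, "NA": np.nan, "": np.nan}

__all__ = [
    "read_map", "write_map", "read_genotypes", "write_genotypes",
    "read_phenotypes", "read_phenotypes_wide", "write_phenotypes",
    "read_inputs", "write_trait_matrix", "read_trait_matrix",
    "write_model_json", "read_model_json", "write_truth_json",
]


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    missing = {"marker", "chrom", "pos_cM"} - set(df.columns)
    if missing:
        raise ValueError(f"map file lacks columns: {sorted(missing)}")
    return GeneticMap.from_frame(df)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(
    path, code_map: dict[str, float] | None = None
) -> MarkerGenotypes:
    """Genotype CSV -> MarkerGenotypes; non-parental codes become missing.

    Heterozygous or otherwise unmapped codes (e.g. "H") are coerced to
    missing with a logged count: the RIL model space has two states.
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "line":
        raise ValueError("first genotype column must be 'line'")
    if df["line"].duplicated().any():
        dups = df["line"][df["line"].duplicated()].tolist()
        raise ValueError(f"duplicate line identifiers: {dups}")
    markers = list(df.columns[1:])
    raw = df[markers].to_numpy()
    codes = np.full(raw.shape, np.nan)
    coerced = 0
    for token, value in code_map.items():
        codes[raw == token] = value
    unknown = ~np.isin(raw, list(code_map)) & (raw != "")
    coerced = int(unknown.sum())
    if coerced:
        logger.info("coerced %d non-parental genotype calls to missing",
                    coerced)
    return MarkerGenotypes(df["line"].tolist(), markers, codes)


def write_genotypes(geno: MarkerGenotypes, path) -> None:
    inv = {1.0: "A", -1.0: "B"}
    rows = []
    for i, line in enumerate(geno.lines):
        rows.append(
            [line]
            + [
                inv.get(v, "NA") if not np.isnan(v) else "NA"
                for v in geno.codes[i]
            ]
        )
    pd.DataFrame(rows, columns=["line"] + list(geno.marker_names)).to_csv(
        path, index=False
    )


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"line": str, "block": str, "trait": str}
    )
    missing = {"line", "block", "trait", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    if df.duplicated(["line", "block", "trait"]).any():
        raise ValueError("duplicate (line, block, trait) records")
    return df


def read_phenotypes_wide(path) -> pd.DataFrame:
    """Wide phenotype CSV (line, block, one column per trait) -> long."""
    df = pd.read_csv(path, dtype={"line": str, "block": str})
    traits = [c for c in df.columns if c not in ("line", "block")]
    long = df.melt(
        id_vars=["line", "block"], value_vars=traits,
        var_name="trait", value_name="value",
    )
    return long.dropna(subset=["value"]).reset_index(drop=True)


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_inputs(map_path, geno_path, pheno_path):
    """Read and cross-validate the three standard inputs together.

    All validation failures are collected and reported in one error.
    """
    problems = []
    gmap = geno = pheno = None
    try:
        gmap = read_map(map_path)
    except Exception as e:  # noqa: BLE001 - collected and re-raised
        problems.append(f"map: {e}")
    try:
        geno = read_genotypes(geno_path)
    except Exception as e:  # noqa: BLE001
        problems.append(f"genotypes: {e}")
    try:
        pheno = read_phenotypes(pheno_path)
    except Exception as e:  # noqa: BLE001
        problems.append(f"phenotypes: {e}")
    if gmap is not None and geno is not None:
        extra = set(geno.marker_names) - set(gmap.marker_names)
        if extra:
            problems.append(
                f"genotype columns absent from map: {sorted(extra)[:5]}"
            )
        elif geno.marker_names != gmap.marker_names:
            # same marker set, different order: reorder to map order
            order = [geno.marker_names.index(m) for m in gmap.marker_names]
            geno = MarkerGenotypes(
                list(geno.lines), list(gmap.marker_names),
                geno.codes[:, order],
            )
    if problems:
        raise ValueError("invalid inputs:\n  " + "\n  ".join(problems))
    return gmap, geno, pheno


def write_trait_matrix(tm: TraitMatrix, csv_path, sidecar: dict | None = None):
    """TraitMatrix -> CSV of standardized values + JSON sidecar.

    The sidecar records the per-trait mean/sd used for standardization plus
    any caller-supplied metadata (variance-model choices, heritabilities).
    """
    out = tm.z.copy()
    out.insert(0, "line", tm.lines)
    out.to_csv(csv_path, index=False)
    meta = {
        "traits": tm.traits,
        "mu": {t: tm.mu[t] for t in tm.traits},
        "sigma": {t: tm.sigma[t] for t in tm.traits},
    }
    meta.update(sidecar or {})
    Path(str(csv_path) + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n"
    )


def read_trait_matrix(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, dtype={"line": str})
    return df.set_index("line")


def _model_dict(model: QTLModel) -> dict:
    return {
        "terms": [[c, p] for c, p in model.terms],
        "pairs": [list(p) for p in model.pairs],
        "trait_names": model.trait_names,
        "mu": model.mu.tolist(),
        "beta": model.beta.tolist(),
        "w": model.w.tolist(),
        "sigma": model.sigma.tolist(),
        "n": model.n,
        "loglik": model.loglik,
    }


def write_model_json(model: QTLModel, path, extra: dict | None = None) -> None:
    d = _model_dict(model)
    d.update(extra or {})
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")


def read_model_json(path) -> QTLModel:
    d = json.loads(Path(path).read_text())
    return QTLModel(
        terms=[(str(c), float(p)) for c, p in d["terms"]],
        pairs=[tuple(p) for p in d["pairs"]],
        trait_names=list(d["trait_names"]),
        mu=np.asarray(d["mu"], dtype=float),
        beta=np.asarray(d["beta"], dtype=float).reshape(
            len(d["terms"]), len(d["trait_names"])
        ),
        w=np.asarray(d["w"], dtype=float).reshape(
            len(d["pairs"]), len(d["trait_names"])
        ),
        sigma=np.asarray(d["sigma"], dtype=float),
        n=int(d["n"]),
        loglik=float(d["loglik"]),
    )


def write_truth_json(path, qtl_loci, additive_effects, epistatic_terms=(),
                     trait_names=()) -> None:
    """Simulation ground truth for recovery tests."""
    d = {
        "qtl_loci": [[c, float(p)] for c, p in qtl_loci],
        "additive_effects": np.asarray(additive_effects).tolist(),
        "epistatic_terms": [
            {"pair": list(pr), "effects": np.asarray(w).tolist()}
            for pr, w in epistatic_terms
        ],
        "trait_names": list(trait_names),
    }
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")
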