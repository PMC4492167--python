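"""Simulation studies validating the QTL pipeline end to end.

Two studies are packaged here so that drivers, tests and the reproduction
script all run the identical computation:

* :func:`null_rejection_rate` — genome-wide false-positive calibration of
  the resampled score-statistic threshold: many independent no-QTL datasets,
  one threshold each, and the fraction whose genome-wide maximum exceeds it.
  Under a calibrated procedure that fraction matches the nominal level.
* :func:`recovery_study` — end-to-end parameter recovery on the emulated
  study design (145 RILs, paper-like chromosomes, 4 blocks, 7 correlated
  traits, QTL effects of 0.25-0.40 phenotype sd): simulate, run the full
  phenotype-prep + MT-MIM forward search, and compare recovered effects and
  support intervals against the planted truth.

Planted effects are expressed in raw phenotype-sd units (the simulator's
scale); the analysis operates on standardized fitted genotype values, so the
truth is mapped onto the analysis scale with the standardization sd recorded
by the trait matrix (replicate averaging shrinks residual noise, which makes
analysis-scale effects larger than the raw betas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genmap, mimcore, phenoprep, simdata

__all__ = ["null_rejection_rate", "recovery_study", "prep_trait_matrix"]


def null_rejection_rate(
    n_datasets: int = 200,
    n_lines: int = 145,
    n_chrom: int = 5,
    chrom_length_cM: float = 100.0,
    marker_spacing_cM: float = 10.0,
    alpha: float = 0.15,
    K: int = 200,
    seed: int = 1,
    step: float = 1.0,
) -> dict:
    """Fraction of null datasets whose genome-wide max score beats the
    resampled threshold at level ``alpha``.

    Each dataset: RIL genomes on the given map, one standard-normal trait
    with no genetic signal, an intercept-only base model, a fresh K-resample
    threshold, and the observed genome-wide maximum score statistic.
    """
    n_markers = int(round(chrom_length_cM / marker_spacing_cM)) + 1
    gmap = simdata.simulate_map(
        n_chrom, chrom_length_cM, n_markers, spacing="uniform", seed=seed
    )
    rejections = 0
    maxima_records = []
    for i in range(n_datasets):
        ss = np.random.SeedSequence([seed, i])
        s_geno, s_trait, s_resample = [
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
        ]
        geno, _ = simdata.simulate_ril_genotypes(
            gmap, [], n_lines, seed=s_geno
        )
        probs = genmap.qtl_genotype_probabilities(gmap, geno, step=step)
        y = np.random.default_rng(s_trait).standard_normal(n_lines)
        z, *_ = phenoprep.standardize(y)
        null_model = mimcore.fit_qtl_model(z, probs, [])
        thr = mimcore.resampled_score_threshold(
            z, probs, null_model, alpha=alpha, K=K, seed=s_resample
        )
        scan = mimcore.scan_add_qtl(z, probs, null_model)
        observed_max = float(scan.score.max())
        rejections += observed_max > thr.threshold
        maxima_records.append((observed_max, thr.threshold))
    return {
        "n_datasets": n_datasets,
        "alpha": alpha,
        "rejections": int(rejections),
        "rate": rejections / n_datasets,
        "rate_percent": 100.0 * rejections / n_datasets,
        "records": maxima_records,
    }


def prep_trait_matrix(
    records: pd.DataFrame, select_variance: bool = True
) -> tuple[phenoprep.TraitMatrix, dict]:
    """Run the phenotype-prep stage: per-trait model fit (with optional
    variance-model selection), fitted genotype values, standardization."""
    fitted, meta = {}, {"variance_model": {}, "h2": {}}
    for trait in sorted(records["trait"].unique()):
        homo = phenoprep.fit_trait_model(records, trait, "homoscedastic")
        if select_variance:
            het = phenoprep.fit_trait_model(records, trait, "by_genotype")
            sel = phenoprep.select_variance_model(homo, het)
            fit = sel.fit
            meta["variance_model"][trait] = sel.selected
        else:
            fit = homo
            meta["variance_model"][trait] = "homoscedastic"
        fitted[trait] = phenoprep.genotype_fitted_values(fit)
        meta["h2"][trait] = phenoprep.heritability(records, trait).h2
    return phenoprep.build_trait_matrix(fitted), meta


@dataclass
class RecoveryResult:
    effects: pd.DataFrame    # one row per detected (QTL, trait) truth entry
    detections: pd.DataFrame  # one row per matched QTL detection
    n_reps: int

    @property
    def per_effect_bias(self) -> pd.Series:
        """Mean signed error per planted (QTL, trait) effect across reps."""
        g = self.effects.groupby(["qtl", "trait"])
        counts = g.size()
        bias = g.apply(
            lambda d: float(np.mean(d["estimate"] - d["truth_std"])),
            include_groups=False,
        )
        return bias[counts >= 5]

    @property
    def mean_abs_bias(self) -> float:
        return float(self.per_effect_bias.abs().mean())

    @property
    def interval_coverage(self) -> float:
        return float(self.detections["covered"].mean())


def _draw_architecture(rng, n_chrom, chrom_len, trait_names, sigma):
    """3 planted QTLs (one per chromosome), each hitting 3 of the 7 traits
    with |beta| in [0.25, 0.40] phenotype sd and random sign."""
    T = len(trait_names)
    qtls = []
    beta = np.zeros((n_chrom, T))
    for c in range(n_chrom):
        pos = float(rng.integers(20, int(chrom_len) - 20))
        qtls.append((str(c + 1), pos))
        traits_hit = rng.choice(T, size=3, replace=False)
        for t in traits_hit:
            beta[c, t] = rng.choice([-1, 1]) * rng.uniform(0.25, 0.40)
    return qtls, beta


def recovery_study(
    n_reps: int = 20,
    n_chrom: int = 3,
    n_lines: int = 145,
    chrom_length_cM: float = 178.75,
    markers_per_chrom: int = 30,
    K: int = 200,
    alpha_main: float = 0.15,
    seed: int = 1,
    select_variance: bool = False,
) -> RecoveryResult:
    """End-to-end effect and position recovery on the emulated study design.

    Per replicate: simulate the population and phenotypes, run phenotype
    prep and the MT-MIM forward search (1 cM grid, resampled thresholds),
    match each fitted QTL to the planted QTL on its chromosome, and record
    effect estimates against the analysis-scale truth plus whether the true
    position falls inside the 1.5-LOD support interval.
    """
    trait_names, C = simdata.table1_like_correlation()
    eff_rows, det_rows = [], []
    for rep in range(n_reps):
        ss = np.random.SeedSequence([seed, 7, rep])
        s_arch, s_geno, s_pheno, s_search = [
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
        ]
        rng = np.random.default_rng(s_arch)
        gmap = simdata.simulate_map(
            n_chrom, chrom_length_cM, markers_per_chrom, seed=0
        )
        qtls, beta = _draw_architecture(
            rng, n_chrom, chrom_length_cM, trait_names, C
        )
        # Planted betas are in progeny-mean sd units (the scale QTL effects
        # are reported on): with 4 replicates averaged, a replicate-level
        # residual covariance of 4C leaves the line-mean residuals with
        # covariance C (unit diagonal), so the line-level trait sd is ~1.
        n_reps_block = 4
        arch = simdata.SimArchitecture(
            qtl_loci=qtls,
            additive_effects=beta,
            residual_covariance=n_reps_block * C,
            trait_names=trait_names,
            n_replicates=n_reps_block,
            seed=s_pheno,
        )
        geno, codes = simdata.simulate_ril_genotypes(
            gmap, qtls, n_lines, seed=s_geno
        )
        records = simdata.simulate_phenotypes(codes, arch)
        tm, _ = prep_trait_matrix(records, select_variance=select_variance)
        probs = genmap.qtl_genotype_probabilities(gmap, geno, step=1.0)
        model = mimcore.forward_search(
            tm.z, probs, alpha_main=alpha_main, rounds=3, K=K, seed=s_search
        )
        truth_by_chrom = {c: (p, j) for j, (c, p) in enumerate(qtls)}
        for k, (c, p) in enumerate(model.terms):
            if c not in truth_by_chrom:
                continue
            true_pos, qtl_idx = truth_by_chrom[c]
            iv = mimcore.support_interval(tm.z, probs, model, k, gmap=gmap)
            covered = bool(iv.left - 1e-9 <= true_pos <= iv.right + 1e-9)
            det_rows.append(
                {
                    "rep": rep, "qtl": qtl_idx, "chrom": c,
                    "true_pos": true_pos, "est_pos": p,
                    "covered": covered, "flat": iv.flat,
                }
            )
            for t, tname in enumerate(trait_names):
                truth_std = beta[qtl_idx, t] / tm.sigma[tname]
                col = model.trait_names.index(tname)
                eff_rows.append(
                    {
                        "rep": rep, "qtl": qtl_idx, "trait": tname,
                        "estimate": float(model.beta[k, col]),
                        "truth_std": float(truth_std),
                        "truth_raw": float(beta[qtl_idx, t]),
                    }
                )
    return RecoveryResult(
        pd.DataFrame(eff_rows), pd.DataFrame(det_rows), n_reps
    )
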