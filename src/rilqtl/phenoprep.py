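"""Per-trait phenotypic models, standardization, heritability, correlations.

Each trait is fitted with the two-way fixed-effects model
    y_ib = mu + block_b + genotype_i + eps_ib
by maximum likelihood, either with a constant residual variance or with a
per-genotype residual variance (heteroscedastic), and the two variance
structures are compared by a likelihood-ratio test. QTL mapping downstream
consumes one fitted value per line (mu + G_j) from the better model,
standardized to mean 0 / sd 1 (sample sd, n-1 denominator).

Broad-sense heritability is computed from the ANOVA mean squares as
h^2 = sigma_G^2 / (sigma_G^2 + sigma_E^2) with sigma_G^2 = (MS_G - MS_E)/r,
truncated at zero. Phenotypic correlations are Pearson correlations of the
per-line fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitModelFit",
    "VarianceModelSelection",
    "TraitMatrix",
    "HeritabilityResult",
    "CorrelationMatrix",
    "fit_trait_model",
    "select_variance_model",
    "genotype_fitted_values",
    "standardize",
    "build_trait_matrix",
    "heritability",
    "correlations",
]

_MAX_IRLS_SWEEPS = 200
_IRLS_TOL = 1e-10


@dataclass
class TraitModelFit:
    trait: str
    mu: float
    block_effects: pd.Series      # sum-to-zero
    genotype_effects: pd.Series   # sum-to-zero
    sigma2: float | pd.Series     # scalar or per-genotype
    loglik: float
    variance_model: str           # "homoscedastic" | "by_genotype"
    n_obs: int


@dataclass
class VarianceModelSelection:
    statistic: float
    df: int
    p_value: float
    selected: str
    fit: TraitModelFit


@dataclass
class TraitMatrix:
    """Per-line fitted trait values and their standardized versions."""

    lines: list[str]
    traits: list[str]
    values: pd.DataFrame  # line x trait fitted values
    z: pd.DataFrame       # standardized (mean 0, sample sd 1)
    mu: pd.Series         # per-trait mean used
    sigma: pd.Series      # per-trait sd used


@dataclass
class HeritabilityResult:
    trait: str
    ms_g: float
    ms_e: float
    r: int
    sigma2_g: float
    sigma2_e: float
    h2: float


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    significant: pd.DataFrame  # p < 0.01 flags


def _design(sub: pd.DataFrame):
    """Sum-to-zero coded design for mu + block + genotype."""
    lines = sorted(sub["line"].unique())
    blocks = sorted(sub["block"].unique())
    J, B = len(lines), len(blocks)
    if B < 2:
        raise ValueError("need at least 2 blocks")
    li = sub["line"].map({g: k for k, g in enumerate(lines)}).to_numpy()
    bi = sub["block"].map({b: k for k, b in enumerate(blocks)}).to_numpy()
    n = len(sub)
    X = np.zeros((n, 1 + (B - 1) + (J - 1)))
    X[:, 0] = 1.0
    for k in range(B - 1):
        X[bi == k, 1 + k] = 1.0
        X[bi == B - 1, 1 + k] = -1.0
    for k in range(J - 1):
        X[li == k, B + k] = 1.0
        X[li == J - 1, B + k] = -1.0
    return X, lines, blocks, li, bi


def _unpack(beta, lines, blocks):
    B, J = len(blocks), len(lines)
    mu = beta[0]
    be = np.append(beta[1:B], -beta[1:B].sum())
    ge = np.append(beta[B : B + J - 1], -beta[B : B + J - 1].sum())
    return mu, pd.Series(be, index=blocks), pd.Series(ge, index=lines)


def fit_trait_model(
    records: pd.DataFrame, trait: str, variance_model: str = "homoscedastic"
) -> TraitModelFit:
    """ML fit of y = mu + block + genotype (+ per-genotype variances).

    Under ``by_genotype`` the per-genotype variances are estimated jointly
    with the mean structure by iteratively reweighted ML starting from the
    homoscedastic solution, so its log-likelihood can never fall below the
    homoscedastic one.
    """
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait}")
    if sub.duplicated(["line", "block"]).any():
        raise ValueError("duplicate (line, block) observations")
    X, lines, blocks, li, _ = _design(sub)
    y = sub["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        counts = sub.groupby("line")["block"].nunique()
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"singular design; genotypes observed in <2 blocks: {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    if variance_model == "homoscedastic":
        mu, be, ge = _unpack(beta, lines, blocks)
        return TraitModelFit(trait, float(mu), be, ge, s2, float(ll),
                             "homoscedastic", n)
    if variance_model != "by_genotype":
        raise ValueError("variance_model must be homoscedastic or by_genotype")
    J = len(lines)
    floor = 1e-10 * max(s2, 1e-30)
    sig2 = np.full(J, s2)
    prev = -np.inf
    for _ in range(_MAX_IRLS_SWEEPS):
        # variance update given current mean structure
        for j in range(J):
            m = li == j
            sig2[j] = max(float(np.mean(resid[m] ** 2)), floor)
        w = 1.0 / sig2[li]
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        resid = y - X @ beta
        ll_het = -0.5 * (
            n * np.log(2 * np.pi)
            + float(np.sum(np.log(sig2[li])))
            + float(np.sum(resid**2 / sig2[li]))
        )
        if abs(ll_het - prev) < _IRLS_TOL * (1 + abs(ll_het)):
            break
        prev = ll_het
    for j in range(J):  # final variance update so ll is at its maximum in sig2
        m = li == j
        sig2[j] = max(float(np.mean(resid[m] ** 2)), floor)
    ll_het = -0.5 * (
        n * np.log(2 * np.pi)
        + float(np.sum(np.log(sig2[li])))
        + float(np.sum(resid**2 / sig2[li]))
    )
    mu, be, ge = _unpack(beta, lines, blocks)
    return TraitModelFit(
        trait, float(mu), be, ge, pd.Series(sig2, index=lines),
        float(ll_het), "by_genotype", n,
    )


def select_variance_model(
    fit_homo: TraitModelFit, fit_het: TraitModelFit, alpha: float = 0.05
) -> VarianceModelSelection:
    """LRT between the nested variance structures; df = J - 1."""
    if fit_homo.trait != fit_het.trait:
        raise ValueError("fits are for different traits")
    if fit_homo.variance_model != "homoscedastic" or (
        fit_het.variance_model != "by_genotype"
    ):
        raise ValueError("expected one homoscedastic and one by_genotype fit")
    stat = 2.0 * (fit_het.loglik - fit_homo.loglik)
    df = len(fit_het.genotype_effects) - 1
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    selected = "by_genotype" if p < alpha else "homoscedastic"
    return VarianceModelSelection(
        float(stat), df, p, selected,
        fit_het if selected == "by_genotype" else fit_homo,
    )


def genotype_fitted_values(fit: TraitModelFit) -> pd.Series:
    """Per-line fitted value mu + G_j (block effects average out)."""
    return fit.mu + fit.genotype_effects


def standardize(values: pd.Series | np.ndarray):
    """Center and scale to sample sd 1 (n-1 denominator).

    Returns (z, mu, sigma); raises on constant input.
    """
    v = np.asarray(values, dtype=float)
    mu = float(np.mean(v))
    sigma = float(np.std(v, ddof=1))
    if sigma <= 0 or not np.isfinite(sigma):
        raise ValueError("cannot standardize a constant trait")
    z = (v - mu) / sigma
    if isinstance(values, pd.Series):
        z = pd.Series(z, index=values.index)
    return z, mu, sigma


def build_trait_matrix(fitted: dict[str, pd.Series]) -> TraitMatrix:
    """Assemble and standardize per-line fitted values for several traits."""
    values = pd.DataFrame(fitted)
    mus, sigmas, zcols = {}, {}, {}
    for t in values.columns:
        z, mu, sigma = standardize(values[t])
        zcols[t], mus[t], sigmas[t] = z, mu, sigma
    return TraitMatrix(
        lines=list(values.index),
        traits=list(values.columns),
        values=values,
        z=pd.DataFrame(zcols),
        mu=pd.Series(mus),
        sigma=pd.Series(sigmas),
    )


def heritability(records: pd.DataFrame, trait: str) -> HeritabilityResult:
    """Broad-sense heritability from the block + genotype ANOVA.

    sigma_G^2 = (MS_G - MS_E) / r (truncated at 0), sigma_E^2 = MS_E,
    h^2 = sigma_G^2 / (sigma_G^2 + sigma_E^2).
    """
    sub = records[records["trait"] == trait]
    X, lines, blocks, li, bi = _design(sub)
    B, J = len(blocks), len(lines)
    r = int(round(len(sub) / J))
    if r < 2:
        raise ValueError("heritability needs >= 2 replications")
    y = sub["value"].to_numpy(dtype=float)
    # sequential sums of squares: blocks, then genotypes, then error
    Xb = X[:, :B]  # intercept + block contrasts
    bb, *_ = np.linalg.lstsq(Xb, y, rcond=None)
    rss_blocks = float(np.sum((y - Xb @ bb) ** 2))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ beta) ** 2))
    df_e = len(y) - X.shape[1]
    if df_e <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_g = (rss_blocks - rss_full) / (J - 1)
    ms_e = rss_full / df_e
    s2g = max((ms_g - ms_e) / r, 0.0)
    h2 = s2g / (s2g + ms_e) if (s2g + ms_e) > 0 else 0.0
    return HeritabilityResult(trait, ms_g, ms_e, r, s2g, ms_e, h2)


def correlations(tm: TraitMatrix, alpha: float = 0.01) -> CorrelationMatrix:
    """Pairwise Pearson correlations of per-line fitted values."""
    V = tm.values
    n = len(V)
    if n < 3:
        raise ValueError("need at least 3 lines")
    if (V.std(ddof=1) <= 0).any():
        bad = V.columns[(V.std(ddof=1) <= 0)].tolist()
        raise ValueError(f"zero-variance traits: {bad}")
    T = len(tm.traits)
    r = np.eye(T)
    p = np.zeros((T, T))
    for a in range(T):
        for b in range(a + 1, T):
            res = stats.pearsonr(V.iloc[:, a], V.iloc[:, b])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    idx = tm.traits
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    np.fill_diagonal(pdf.values, 0.0)
    return CorrelationMatrix(rdf, pdf, n, pdf < alpha)
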