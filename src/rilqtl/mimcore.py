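"""Multiple interval mapping (MIM) and its multi-trait extension (MT-MIM).

The model for standardized traits z (lines x traits) is the Cockerham-coded
multiple-QTL regression
    z_ti = mu_t + sum_r beta_tr x_ir + sum_{r<l} w_trl x_ir x_il + eps_ti,
eps_ti ~ MVN(0, Sigma_eps), where x_ir is +1/-1 for the two RIL homozygote
classes. Unobserved QTL genotypes are handled by Haley-Knott regression:
x_ir is replaced by its conditional expectation 2 q_ir - 1 given flanking
marker data, and the model is fitted by per-trait least squares with a
shared design. LOD scores between nested models use the determinant ratio
LOD = (n/2) log10(|Sigma_0| / |Sigma_1|), which for one trait reduces to the
familiar (n/2) log10(RSS_0 / RSS_1); single-trait MIM is exactly the T = 1
case of the same code path.

Genome-wide significance for the forward searches comes from resampled
score statistics: per candidate position the per-line score contributions
u_i = c~_i * e~_i (candidate column residualized against the current design,
times the whitened current-model residual row) are perturbed by one shared
standard-normal weight g_i per line — the same weights across positions and
traits within a resample, preserving genome-wide and cross-trait dependence
— and the genome-wide maximum statistic is recomputed per resample. The
threshold is the empirical (1 - alpha) quantile of those maxima; no model
refitting is needed, which is what makes the scheme cheap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap, GenotypeProbabilities

logger = logging.getLogger(__name__)

__all__ = [
    "QTLModel",
    "ScanProfile",
    "ThresholdResult",
    "EffectTest",
    "SupportInterval",
    "design_matrix",
    "fit_model",
    "fit_qtl_model",
    "lod_compare",
    "scan_add_qtl",
    "resampled_score_threshold",
    "forward_search",
    "refine_positions",
    "epistasis_search",
    "effect_pvalues",
    "qtl_r2",
    "support_interval",
]

_RANK_TOL = 1e-8
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "+"))


def star_code(p: float) -> str:
    for level, code in STAR_LEVELS:
        if p < level:
            return code
    return ""


# ---------------------------------------------------------------------------
# model containers


@dataclass
class QTLModel:
    """A fitted multiple-QTL model (MT-MIM; single-trait MIM when T = 1)."""

    terms: list[tuple[str, float]]            # (chrom, pos cM), on the grid
    pairs: list[tuple[int, int]]              # epistatic index pairs, r < l
    trait_names: list[str]
    mu: np.ndarray                            # (T,)
    beta: np.ndarray                          # (m, T) additive effects
    w: np.ndarray                             # (n_pairs, T) epistatic effects
    sigma: np.ndarray                         # (T, T) residual covariance
    n: int
    loglik: float

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def __post_init__(self):
        for r, l in self.pairs:
            if not (0 <= r < len(self.terms) and 0 <= l < len(self.terms)):
                raise ValueError("epistatic pair references a missing term")


@dataclass
class ScanProfile:
    grid: pd.DataFrame        # chrom, pos_cM of scanned positions
    lod: np.ndarray
    score: np.ndarray


@dataclass
class ThresholdResult:
    alpha: float
    n_resamples: int
    seed: int
    threshold: float          # score-statistic scale
    lod_equivalent: float
    maxima: np.ndarray        # the K resampled genome-wide maxima


@dataclass
class EffectTest:
    kind: str                 # "additive" | "epistatic"
    index: int                # term index or pair index
    trait: str
    estimate: float
    p_value: float
    stars: str


@dataclass
class SupportInterval:
    term_index: int
    chrom: str
    peak_pos: float
    peak_lod: float
    left: float
    right: float
    left_marker: str | None = None
    right_marker: str | None = None
    flat: bool = False


# ---------------------------------------------------------------------------
# design and fitting


def _term_columns(probs: GenotypeProbabilities, terms) -> np.ndarray:
    idx = [probs.position_index(c, p) for c, p in terms]
    return probs.xhat[:, idx] if idx else np.empty((len(probs.lines), 0))


def design_matrix(
    probs: GenotypeProbabilities, terms, epistatic_pairs=()
) -> np.ndarray:
    """Haley-Knott design: additive columns xhat = 2q - 1, epistasis columns
    as elementwise products of the two additive columns (no intercept)."""
    A = _term_columns(probs, terms)
    cols = [A]
    for r, l in epistatic_pairs:
        cols.append((A[:, r] * A[:, l])[:, None])
    return np.hstack(cols) if cols else A


@dataclass
class _LinFit:
    coef: np.ndarray        # (1 + p, T) including intercept row 0
    resid: np.ndarray       # (n, T)
    sigma: np.ndarray       # (T, T), n denominator
    loglik: float
    logdet: float           # log |sigma|
    Xc: np.ndarray          # centered design without intercept


def fit_model(Z: np.ndarray, X: np.ndarray) -> _LinFit:
    """Per-trait least squares with shared design (intercept included).

    Sigma_hat = E'E / n; log-likelihood is the profiled multivariate-normal
    value -n/2 (T log 2pi + log|Sigma_hat| + T). With an empty design this
    reduces to the sample covariance of Z (n denominator).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, T = Z.shape
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        X = np.empty((n, 0))
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError("more design columns than residual degrees of freedom")
    X1 = np.column_stack([np.ones(n), X])
    # rank check with column identification
    _, Rq = np.linalg.qr(X1)
    diag = np.abs(np.diag(Rq))
    bad = np.flatnonzero(diag < _RANK_TOL * max(diag.max(), 1.0))
    if bad.size:
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns (0-based, after "
            f"intercept): {[int(b) - 1 for b in bad]}"
        )
    coef, *_ = np.linalg.lstsq(X1, Z, rcond=None)
    E = Z - X1 @ coef
    S = (E.T @ E) / n
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        # residuals (numerically) degenerate; floor for a finite loglik
        logdet = float(np.sum(np.log(np.maximum(np.diag(S), 1e-300))))
    ll = -0.5 * n * (T * np.log(2 * np.pi) + logdet + T)
    return _LinFit(coef, E, S, float(ll), float(logdet), X - X.mean(axis=0))


def fit_qtl_model(
    Z, probs: GenotypeProbabilities, terms, pairs=()
) -> QTLModel:
    """Fit the MT-MIM model at the given positions/pairs; returns QTLModel."""
    Zm, names = _as_matrix(Z)
    terms = [(str(c), float(p)) for c, p in terms]
    pairs = [tuple(sorted(pr)) for pr in pairs]
    X = design_matrix(probs, terms, pairs)
    fit = fit_model(Zm, X)
    m = len(terms)
    return QTLModel(
        terms=terms,
        pairs=pairs,
        trait_names=names,
        mu=fit.coef[0],
        beta=fit.coef[1 : 1 + m],
        w=fit.coef[1 + m :],
        sigma=fit.sigma,
        n=Zm.shape[0],
        loglik=fit.loglik,
    )


def _as_matrix(Z) -> tuple[np.ndarray, list[str]]:
    if isinstance(Z, pd.DataFrame):
        return Z.to_numpy(dtype=float), [str(c) for c in Z.columns]
    if isinstance(Z, pd.Series):
        return Z.to_numpy(dtype=float)[:, None], [str(Z.name or "trait")]
    Zm = np.asarray(Z, dtype=float)
    if Zm.ndim == 1:
        Zm = Zm[:, None]
    return Zm, [f"trait{t + 1}" for t in range(Zm.shape[1])]


def _refit(Z, probs, model: QTLModel) -> QTLModel:
    return fit_qtl_model(Z, probs, model.terms, model.pairs)


def lod_compare(fit0: QTLModel, fit1: QTLModel) -> float:
    """LOD = (n/2) log10(|Sigma_0| / |Sigma_1|) for nested models.

    For T = 1 this equals (n/2) log10(RSS_0 / RSS_1); it is invariant under
    any invertible linear transformation of the trait block.
    """
    if fit0.n != fit1.n or fit0.trait_names != fit1.trait_names:
        raise ValueError("models were fitted to different data")
    t0 = set(fit0.terms)
    t1 = set(fit1.terms)
    if not t0 <= t1:
        raise ValueError("models are not nested")
    p0 = {tuple(sorted((fit0.terms[r], fit0.terms[l]))) for r, l in fit0.pairs}
    p1 = {tuple(sorted((fit1.terms[r], fit1.terms[l]))) for r, l in fit1.pairs}
    if not p0 <= p1:
        raise ValueError("models are not nested (epistatic terms)")
    s0, d0 = np.linalg.slogdet(fit0.sigma)
    s1, d1 = np.linalg.slogdet(fit1.sigma)
    lod = fit0.n / 2.0 * (d0 - d1) / np.log(10.0)
    return float(lod)


# ---------------------------------------------------------------------------
# scanning machinery


class _ScanState:
    """Precomputed quantities for scanning one-more-QTL against a base model.

    C: candidate additive columns (n x P) at every scanned grid position,
    residualized against the base design; Ew: whitened base-model residuals.
    """

    def __init__(self, Z, probs: GenotypeProbabilities, model: QTLModel):
        Zm, names = _as_matrix(Z)
        self.Zm, self.names = Zm, names
        n, T = Zm.shape
        X0 = design_matrix(probs, model.terms, model.pairs)
        fit0 = fit_model(Zm, X0)
        self.fit0 = fit0
        self.n, self.T = n, T
        used = {probs.position_index(c, p) for c, p in model.terms}
        keep = np.array(
            [j for j in range(len(probs.grid)) if j not in used], dtype=int
        )
        self.grid = probs.grid.iloc[keep].reset_index(drop=True)
        C = probs.xhat[:, keep]
        X1 = np.column_stack([np.ones(n), X0])
        # residualize candidates against the base design (incl. intercept)
        Q, _ = np.linalg.qr(X1)
        self.C = C - Q @ (Q.T @ C)
        self.cpp = np.einsum("ij,ij->j", self.C, self.C)
        self.ok = self.cpp > _RANK_TOL * n
        # whitened residuals for the score statistic
        S0 = fit0.sigma
        w, V = np.linalg.eigh(S0)
        w = np.maximum(w, 1e-12 * max(w.max(), 1e-300))
        self.Ew = fit0.resid @ (V / np.sqrt(w)) @ V.T
        self.E = fit0.resid

    def observed_scores(self) -> np.ndarray:
        U = self.C.T @ self.Ew                     # (P, T)
        s = np.einsum("pt,pt->p", U, U)
        out = np.zeros_like(s)
        np.divide(s, self.cpp, out=out, where=self.ok)
        return out

    def lods(self) -> np.ndarray:
        V = self.C.T @ self.E                      # (P, T)
        S0 = self.fit0.sigma * self.n
        dets0 = np.linalg.det(S0)
        S1 = S0[None] - (
            V[:, :, None] * V[:, None, :]
            / np.where(self.ok, self.cpp, 1.0)[:, None, None]
        )
        dets1 = np.linalg.det(S1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = self.n / 2.0 * np.log10(dets0 / np.maximum(dets1, 1e-300))
        lod[~self.ok] = 0.0
        return np.maximum(lod, 0.0)

    def resampled_maxima(self, K: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        maxima = np.empty(K)
        for k in range(K):
            g = rng.standard_normal(self.n)
            M = self.C.T @ (g[:, None] * self.Ew)  # (P, T)
            s = np.einsum("pt,pt->p", M, M)
            out = np.zeros_like(s)
            np.divide(s, self.cpp, out=out, where=self.ok)
            maxima[k] = out.max()
        return maxima


def scan_add_qtl(Z, probs: GenotypeProbabilities, model: QTLModel) -> ScanProfile:
    """LOD and score statistic for adding one QTL at every free grid position."""
    st = _ScanState(Z, probs, model)
    return ScanProfile(grid=st.grid, lod=st.lods(), score=st.observed_scores())


def resampled_score_threshold(
    Z,
    probs: GenotypeProbabilities,
    model: QTLModel,
    alpha: float,
    K: int = 1000,
    seed: int = 0,
) -> ThresholdResult:
    """Genome-wide threshold from K wild-bootstrap resamples of the scores.

    Shared N(0,1) weights per line across all positions and traits within a
    resample preserve the dependence structure of the genome-wide maximum.
    """
    if K < 100:
        raise ValueError("K must be >= 100 for a stable tail quantile")
    st = _ScanState(Z, probs, model)
    maxima = st.resampled_maxima(K, seed)
    thr = float(np.quantile(maxima, 1.0 - alpha))
    # chi2_T-scale score ~ 2 ln(10) LOD asymptotically
    lod_eq = thr / (2.0 * np.log(10.0))
    return ThresholdResult(alpha, K, seed, thr, float(lod_eq), maxima)


# ---------------------------------------------------------------------------
# model search


def forward_search(
    Z,
    probs: GenotypeProbabilities,
    alpha_main: float = 0.15,
    rounds: int = 3,
    K: int = 1000,
    seed: int = 0,
) -> QTLModel:
    """Forward search for main-effect QTLs with resampled thresholds.

    Each round adds the genome-wide best position if its score statistic
    exceeds the threshold recomputed against the current model (ties break
    to the first grid position, i.e. lowest chromosome then lowest cM),
    stopping early otherwise; positions are then jointly re-estimated.
    """
    model = fit_qtl_model(Z, probs, [])
    for rnd in range(rounds):
        st = _ScanState(Z, probs, model)
        scores = st.observed_scores()
        maxima = st.resampled_maxima(K, seed + 1000 * rnd)
        thr = float(np.quantile(maxima, 1.0 - alpha_main))
        best = int(np.argmax(scores))
        if scores[best] <= thr:
            logger.info(
                "forward search stopped at round %d (max score %.3f <= "
                "threshold %.3f)", rnd + 1, scores[best], thr,
            )
            break
        pos = (st.grid["chrom"].iloc[best], float(st.grid["pos_cM"].iloc[best]))
        model = fit_qtl_model(Z, probs, model.terms + [pos], model.pairs)
        logger.info("round %d: added QTL at %s:%.1f", rnd + 1, *pos)
    if model.terms:
        model = refine_positions(Z, probs, model)
    return model


def refine_positions(
    Z, probs: GenotypeProbabilities, model: QTLModel, max_sweeps: int = 10
) -> QTLModel:
    """Coordinate-wise re-estimation of QTL positions over their chromosomes.

    Each term is rescanned over its own chromosome holding the others fixed
    and moved to the maximum-likelihood grid position; sweeps repeat until
    no term moves. The full-model log-likelihood never decreases.
    """
    if not model.terms:
        return model
    Zm, _ = _as_matrix(Z)
    current = _refit(Z, probs, model)
    for _ in range(max_sweeps):
        moved = False
        for k in range(len(current.terms)):
            chrom = current.terms[k][0]
            cand_idx = np.flatnonzero(
                (probs.grid["chrom"] == chrom).to_numpy()
            )
            occupied = {
                probs.position_index(c, p)
                for j, (c, p) in enumerate(current.terms)
                if j != k
            }
            best_ll, best_terms = current.loglik, None
            for j in cand_idx:
                if j in occupied:
                    continue
                pos = (chrom, float(probs.grid["pos_cM"].iloc[j]))
                if pos == current.terms[k]:
                    continue
                terms = list(current.terms)
                terms[k] = pos
                try:
                    cand = fit_qtl_model(Z, probs, terms, current.pairs)
                except np.linalg.LinAlgError:
                    continue
                if cand.loglik > best_ll + 1e-10:
                    best_ll, best_terms = cand.loglik, terms
            if best_terms is not None:
                current = fit_qtl_model(Z, probs, best_terms, current.pairs)
                moved = True
        if not moved:
            break
    return current


def epistasis_search(
    Z,
    probs: GenotypeProbabilities,
    model: QTLModel,
    alpha_epi: float = 0.05,
    K: int = 1000,
    seed: int = 0,
) -> QTLModel:
    """Forward search over pairwise interactions among included QTLs.

    Candidate columns are products of the included additive columns; the
    inclusion threshold is the resampled (1 - alpha_epi) quantile of the
    maximum score over the remaining candidate pairs. A retained pair must
    show at least one per-trait epistatic effect with p < 0.05.
    """
    if model.n_terms < 2:
        logger.info("epistasis search skipped: fewer than 2 QTLs in model")
        return model
    Zm, _ = _as_matrix(Z)
    model = _refit(Z, probs, model)
    all_pairs = list(itertools.combinations(range(model.n_terms), 2))
    while True:
        candidates = [p for p in all_pairs if p not in model.pairs]
        if not candidates:
            break
        X0 = design_matrix(probs, model.terms, model.pairs)
        A = _term_columns(probs, model.terms)
        Cand = np.column_stack([A[:, r] * A[:, l] for r, l in candidates])
        fit0 = fit_model(Zm, X0)
        n, T = Zm.shape
        X1 = np.column_stack([np.ones(n), X0])
        Q, _ = np.linalg.qr(X1)
        C = Cand - Q @ (Q.T @ Cand)
        cpp = np.einsum("ij,ij->j", C, C)
        ok = cpp > _RANK_TOL * n
        w, V = np.linalg.eigh(fit0.sigma)
        w = np.maximum(w, 1e-12 * max(w.max(), 1e-300))
        Ew = fit0.resid @ (V / np.sqrt(w)) @ V.T
        U = C.T @ Ew
        s = np.einsum("pt,pt->p", U, U)
        scores = np.zeros_like(s)
        np.divide(s, cpp, out=scores, where=ok)
        rng = np.random.default_rng(seed + 7919 * len(model.pairs))
        maxima = np.empty(K)
        for k in range(K):
            g = rng.standard_normal(n)
            M = C.T @ (g[:, None] * Ew)
            sk = np.einsum("pt,pt->p", M, M)
            out = np.zeros_like(sk)
            np.divide(sk, cpp, out=out, where=ok)
            maxima[k] = out.max()
        thr = float(np.quantile(maxima, 1.0 - alpha_epi))
        best = int(np.argmax(scores))
        if not ok[best] or scores[best] <= thr:
            break
        model = fit_qtl_model(
            Z, probs, model.terms, model.pairs + [candidates[best]]
        )
        logger.info("added epistatic pair %s", candidates[best])
    if model.pairs:
        tests = effect_pvalues(Z, probs, model, K=K, seed=seed + 104729)
        keep = []
        for j, pr in enumerate(model.pairs):
            ps = [
                t.p_value for t in tests
                if t.kind == "epistatic" and t.index == j
            ]
            if any(p < 0.05 for p in ps):
                keep.append(pr)
            else:
                logger.info("dropping pair %s: no significant marginal effect",
                            pr)
        if len(keep) != len(model.pairs):
            model = fit_qtl_model(Z, probs, model.terms, keep)
    return model


def effect_pvalues(
    Z, probs: GenotypeProbabilities, model: QTLModel, K: int = 1000,
    seed: int = 0,
) -> list[EffectTest]:
    """Per-effect p-values via resampled score statistics.

    Each (column, trait) effect is tested by the score statistic of adding
    its column back to the model with that column removed; the null
    distribution comes from wild-bootstrap weights shared across effects
    within a resample. p = (1 + #{resample >= observed}) / (K + 1).
    """
    Zm, names = _as_matrix(Z)
    n, T = Zm.shape
    X = design_matrix(probs, model.terms, model.pairs)
    m = model.n_terms
    kinds = [("additive", j) for j in range(m)] + [
        ("epistatic", j) for j in range(len(model.pairs))
    ]
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((K, n))
    out: list[EffectTest] = []
    for col, (kind, j) in enumerate(kinds):
        rest = [c for c in range(X.shape[1]) if c != col]
        X0 = np.column_stack([np.ones(n), X[:, rest]])
        Q, _ = np.linalg.qr(X0)
        c = X[:, col] - Q @ (Q.T @ X[:, col])
        cpp = float(c @ c)
        E0 = Zm - Q @ (Q.T @ Zm)
        est = model.beta[j] if kind == "additive" else model.w[j]
        if cpp <= _RANK_TOL * n:
            for t in range(T):
                out.append(EffectTest(kind, j, names[t], float(est[t]), 1.0, ""))
            continue
        sig2 = np.einsum("it,it->t", E0, E0) / n
        s_obs = (c @ E0) ** 2 / (cpp * sig2)
        # resampled: (K,T) scores from shared weights
        M = G @ (c[:, None] * E0)               # (K, T)
        s_res = M**2 / (cpp * sig2)[None, :]
        for t in range(T):
            p = (1.0 + np.sum(s_res[:, t] >= s_obs[t])) / (K + 1.0)
            out.append(
                EffectTest(kind, j, names[t], float(est[t]), float(p),
                           star_code(p))
            )
    return out


# ---------------------------------------------------------------------------
# summaries


def qtl_r2(Z, probs: GenotypeProbabilities, model: QTLModel):
    """Per-effect and per-trait total R^2 (percent of phenotypic variance).

    R^2(effect, t) = Var_lines(beta_tr xhat_r) / Var_lines(z_t) * 100 and
    R^2_T(t) uses the full fitted genetic value including non-significant
    effects; variances use the sample (n-1) convention.
    """
    Zm, names = _as_matrix(Z)
    X = design_matrix(probs, model.terms, model.pairs)
    m = model.n_terms
    coefs = np.vstack([model.beta, model.w]) if len(model.pairs) else model.beta
    varz = Zm.var(axis=0, ddof=1)
    per_effect = {}
    for col in range(X.shape[1]):
        contrib = np.outer(X[:, col], coefs[col])
        r2 = contrib.var(axis=0, ddof=1) / varz * 100.0
        key = (
            ("additive", col) if col < m else ("epistatic", col - m)
        )
        per_effect[key] = pd.Series(r2, index=names)
    genetic = X @ coefs if X.size else np.zeros_like(Zm)
    total = pd.Series(genetic.var(axis=0, ddof=1) / varz * 100.0, index=names)
    return per_effect, total


def support_interval(
    Z,
    probs: GenotypeProbabilities,
    model: QTLModel,
    term_index: int,
    drop: float = 1.5,
    gmap: GeneticMap | None = None,
) -> SupportInterval:
    """Drop-LOD support interval for one QTL (default 1.5 LOD, ~95%).

    The term's position is profiled over its chromosome with all other
    terms fixed; the interval is the contiguous grid run around the peak
    with LOD >= peak - drop. A flat profile (range < drop) spans the whole
    chromosome and is flagged. Flanking markers are the nearest map markers
    at or outside each bound when a map is supplied.
    """
    if not 0 <= term_index < model.n_terms:
        raise IndexError("term_index out of range")
    chrom = model.terms[term_index][0]
    cand_idx = np.flatnonzero((probs.grid["chrom"] == chrom).to_numpy())
    occupied = {
        probs.position_index(c, p)
        for j, (c, p) in enumerate(model.terms)
        if j != term_index
    }
    # reference: model without this term (and without its pairs)
    other_terms = [t for j, t in enumerate(model.terms) if j != term_index]
    kept_pairs = []
    for r, l in model.pairs:
        if term_index in (r, l):
            continue
        r2 = r - (r > term_index)
        l2 = l - (l > term_index)
        kept_pairs.append((r2, l2))
    base = fit_qtl_model(Z, probs, other_terms, kept_pairs)
    positions, lods = [], []
    for j in cand_idx:
        if j in occupied:
            continue
        pos = float(probs.grid["pos_cM"].iloc[j])
        terms = list(model.terms)
        terms[term_index] = (chrom, pos)
        try:
            cand = fit_qtl_model(Z, probs, terms, model.pairs)
        except np.linalg.LinAlgError:
            continue
        positions.append(pos)
        lods.append(lod_compare(base, cand))
    positions = np.asarray(positions)
    lods = np.asarray(lods)
    order = np.argsort(positions)
    positions, lods = positions[order], lods[order]
    peak = int(np.argmax(lods))
    flat = (lods.max() - lods.min()) < drop
    if flat:
        logger.warning(
            "flat LOD profile for term %d on chromosome %s; interval spans "
            "the chromosome", term_index, chrom,
        )
        lo, hi = 0, len(positions) - 1
    else:
        cut = lods[peak] - drop
        lo = peak
        while lo > 0 and lods[lo - 1] >= cut:
            lo -= 1
        hi = peak
        while hi < len(positions) - 1 and lods[hi + 1] >= cut:
            hi += 1
    left, right = float(positions[lo]), float(positions[hi])
    lmark = rmark = None
    if gmap is not None:
        mpos = gmap.positions[chrom]
        mnames = gmap.markers[chrom]
        li = np.searchsorted(mpos, left + 1e-9) - 1
        ri = np.searchsorted(mpos, right - 1e-9)
        lmark = mnames[max(li, 0)]
        rmark = mnames[min(ri, len(mnames) - 1)]
    return SupportInterval(
        term_index, chrom, float(positions[peak]), float(lods[peak]),
        left, right, lmark, rmark, flat,
    )
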