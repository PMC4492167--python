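# Methods

## Genetic model and genotype probabilities

The population is a biparental RIL panel: lines are treated as fully
homozygous, coded +1 (parent A) / −1 (parent B). Map distances follow the
Kosambi map function, `r = 0.5 tanh(2d/100)` and `d = 25 ln((1+2r)/(1−2r))`
(d in cM); meiotic recombination fractions are collapsed to RIL
recombination fractions with the Haldane–Waddington infinite-selfing limit
`R = 2r/(1+2r)`. Residual heterozygosity from a finite number of selfing
generations is ignored because the two-state code space cannot represent
it; heterozygous calls in input files are coerced to missing (counted and
logged).

Multilocus RIL genotypes are modelled as a first-order two-state Markov
chain over the ordered loci of each chromosome with per-interval switch
probability `R(r(d))`. Exact selfed-RIL multilocus frequencies are not
Markov, but the chain is the standard interval-mapping approximation and is
also the simulator's generative model, so inference and simulation are
internally consistent. Conditional probabilities `q = P(genotype = +1 |
marker data)` on the scan grid condition on the nearest informative marker
on each side — which equals the full forward–backward solution for a Markov
chain — with one-sided conditioning at chromosome ends and `q = 0.5` on
chromosomes without any informative marker for a line. At marker-coincident
grid points the conditioning distance is exactly zero, so `2q − 1`
reproduces the observed code bit-for-bit; the test suite checks the whole
machinery against exhaustive three-locus enumeration at 1e-12.

The scan grid is the union of all marker positions and step-spaced points
(default 1 cM) between the first and last marker of each chromosome, in the
map's own coordinates. Co-located markers are jittered by +1e-6 cM in file
order so positions are strictly increasing.

## Phenotype models

Each trait is fitted with the two-way fixed-effects model
`y = mu + block + genotype + eps` by maximum likelihood, under either a
constant residual variance or per-genotype variances. Blocks are treated as
fixed. The heteroscedastic fit maximizes the likelihood by coordinate
ascent (weighted least squares alternating with per-genotype variance
updates) starting from the homoscedastic solution, which guarantees its
log-likelihood never falls below the homoscedastic one. Exact joint ML for
per-group variances is unbounded (a genotype whose few replicates happen to
be fitted almost perfectly drives its variance estimate to zero), so
variances are floored at 1e-10 times the homoscedastic ML variance; the
homoscedastic log-likelihood matches `nlme::gls(..., method="ML")` to six
decimals on shared test data.

The two variance structures are compared by a likelihood-ratio test with
J − 1 degrees of freedom (J genotypes). Caveat: with few replicates per
genotype this chi-square reference is strongly anti-conservative — the
fixed-effect count grows with the sample, so the usual asymptotics never
apply, and under a homoscedastic truth the richer model is selected far
more often than the nominal 5%. The misselection is benign for the
downstream pipeline because in a (near-)balanced design the genotype fitted
values `mu + G_j` are nearly invariant to the variance weights; the test
suite asserts that invariance rather than a type-I rate the procedure does
not possess.

QTL mapping consumes one fitted value per line from the selected model,
standardized to mean 0 and sample sd 1 (n − 1 denominator; the convention
is recorded in the trait-matrix sidecar for back-transformation). Broad-
sense heritability uses the ANOVA mean squares, `sigma_G^2 = (MS_G −
MS_E)/r` truncated at zero, `h^2 = sigma_G^2/(sigma_G^2 + MS_E)`.
Phenotypic correlations are Pearson correlations of the per-line fitted
values with two-sided t-test p-values (significance flagged at p < 0.01).

## Path analysis

Direct effects solve the normal equations `R_x P = r_xy` via a stable
solver with explicit condition-number reporting (warning above 1e3);
indirect effects are `r_ii' P_i'`, rows reconstruct `r_iy` exactly for
internally consistent inputs, and `R^2 = sum_i P_i r_iy`. The root-trait
worked example is validated through these identities rather than by
re-deriving the published direct effects: with r(SA, RL) = 0.98 the system
is ill-conditioned (condition number ~645), so 2-dp rounded correlations
cannot reproduce 3-dp path coefficients — the published coefficients
satisfy the published system only to about 0.05 in the residual, which the
tests assert as a bound. Root:shoot ratio is excluded from the default
predictor set because it contributes to both dependent variables. (The
narrative names five root-trait predictors but the published decomposition
uses four; the module accepts any predictor list.)

## QTL engine

Haley–Knott design: additive columns hold `2q − 1`; epistasis columns hold
elementwise products of the two additive columns (products of expectations
rather than expectations of products — the standard Haley–Knott
convention; the discrepancy is second order for dense maps). Fitting is
per-trait least squares with the shared design; `Sigma_hat = E'E/n`; the
log-likelihood is the profiled multivariate-normal value. LOD between
nested models is `(n/2) log10(|Sigma_0|/|Sigma_1|)`, which reduces to the
RSS-ratio form for one trait and is invariant under invertible linear
transformations of the trait block.

Score statistics for adding a column `c`: residualize `c` against the
current design, whiten the current residuals by `Sigma_0^{-1/2}`, and form
`S = ||c~' E_w||^2 / (c~'c~)`, asymptotically chi-square with T degrees of
freedom under the null. The genome-wide threshold multiplies the per-line
score contributions by shared standard-normal wild-bootstrap weights — the
same weight vector across positions and traits within one resample, which
preserves the dependence structure of the genome-wide maximum — recomputes
the maximum per resample, and takes the empirical (1 − α) quantile of K
maxima (default K = 1000; studies and tests use K = 200). Thresholding on
the score scale avoids any refitting; the included-QTL model is then fitted
by least squares.

The forward search adds at most one QTL per round (up to 3 rounds, early
stop when the best score fails its freshly computed threshold; ties break
to the first grid position in map order, i.e. lowest chromosome then lowest
cM), then re-estimates all positions coordinate-wise (each term rescanned
over its own chromosome holding the others fixed, repeated to a fixed point
or 10 sweeps; the full-model likelihood is non-decreasing by construction).
The epistasis search tests all pairwise interactions among included QTLs
against a resampled threshold at the 5% level, maxima taken over the
candidate pairs, and retains a pair only if at least one of its per-trait
epistatic effects is significant at p < 0.05 (the retention rule is read as
applying to the pair's own per-trait effects, not to the main effects of
the participating QTLs — the other reading is noted as plausible).

Per-effect p-values come from the same wild-bootstrap scheme applied to the
single-effect score statistic under the model with that column removed,
`p = (1 + #{resample >= observed})/(K + 1)`, with stars at 0.1/0.05/0.01/
0.001. R² of an effect is the variance of its fitted contribution over the
variance of the trait (sample variances, ×100); the per-trait total R²_T
uses the full fitted genetic value including non-significant effects.
Support intervals profile one term's position over its chromosome with the
rest of the model fixed and take the contiguous grid run within 1.5 LOD of
the peak (≈95% nominal); flat profiles (range < drop) span the chromosome
and are flagged. Flanking markers are the nearest map markers at or outside
each bound.

## Simulator and what the validation studies show

The simulator draws RIL genomes from the same two-state chain the engine
assumes (markers and QTL pseudo-loci merged into one ordered chain; true
QTL codes returned separately) and phenotypes from the generative twin of
the MT-MIM model, with fixed block shifts (default −0.3, −0.1, 0.1, 0.3 sd
across 4 replicates), multivariate-normal residuals per line × replicate,
optional per-line lognormal residual-sd multipliers (geometric sd 1.5 when
enabled) and optional missingness. The default study emulation is 145
lines, 10 chromosomes × 178.75 cM, 292 markers (~6.1 cM spacing), 7 traits
whose residual correlation matrix mirrors the published trait-correlation
structure (eigenvalue-floored at 1e-3 and rescaled to unit diagonal, since
the printed 2-dp matrix is slightly indefinite).

Planted QTL effects are expressed in progeny-mean sd units — the scale QTL
effects are reported on. With 4 replicates averaged into one fitted value
per line, a replicate-level residual covariance of 4C leaves the line-mean
residuals with covariance C (unit diagonal), so planted betas of 0.25–0.40
land on the analysis scale at ~0.3 sd (realized mean 0.30 in the recovery
study). Consequence of the QTL-only architecture: there is no polygenic
background term, so simulated broad-sense heritabilities are small (only
planted QTLs contribute genetic variance), unlike real maize seedling
traits where background variation dominates. Matching effect sizes,
per-QTL variance shares and realistic heritabilities simultaneously would
require such a background component, which is outside this architecture.
Passing recovery tests therefore demonstrate correctness of the inference
under its own generative assumptions — Markov genomes, Gaussian residuals,
no genotyping error, no selective genotyping — not robustness to their
violation.

Problem sizes used by the packaged studies: threshold calibration runs 200
null datasets (145 lines, 5 × 100 cM, 10 cM markers, one trait, K = 200;
measured rejection 12% at the nominal 15%); the recovery study runs 20
replicates of a 3-chromosome version of the study design (K = 200; measured
mean |per-effect bias| 0.031 sd, 1.5-LOD coverage 91.7%). These sizes are
the package's defaults for its validation studies; the full 10-chromosome
emulation is exercised by the analysis drivers.

## Numerical choices

Rank deficiency in designs is detected by QR with relative tolerance 1e-8
and reported with the offending columns; candidate scan columns collinear
with the current design (residual norm below tolerance) get score and LOD
0 rather than an error. Degenerate residual covariances are floored inside
log-determinants. Quantiles of resampled maxima use the default linear
empirical quantile. Randomness flows exclusively through explicit integer
seeds (numpy `SeedSequence` spawning inside the studies); there is no
global random state anywhere.

## Known limitations

Besides the simulator idealizations above: the three-rounds forward search
caps main-effect models at three QTLs (an architecture with more planted
QTLs than rounds leaves the remainder to the single-trait scans, as the
analysis drivers illustrate); drop-1.5-LOD intervals are approximate and
tend to narrow for very strong or multi-trait signals; the variance-model
LRT over-selects the heteroscedastic model at realistic replication (see
above); and the wild-bootstrap scheme assumes exchangeable per-line score
contributions, i.e. no family or spatial structure among lines.
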