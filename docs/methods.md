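# Methods

## Model

Gene-expression evolution for a pair of genes is modeled as bivariate
Brownian Motion (BM) on a rooted time tree. With species covariance matrix
C (C_ij = root-to-MRCA depth, time units) and evolutionary rate matrix R
(2×2 positive definite; per-unit-time trait variances on the diagonal,
trait covariance off it), the 2n tip observations are multivariate normal:

    Cov(x_{a,i}, x_{b,j}) = R_ab · C_ij + 1{a=b, i=j} · se_{a,i}²

with mean θ_a for trait a (the root state). Measurement error `se` is the
standard error of the per-species replicate mean on the normalized scale.
The evolutionary correlation ρ_C = r12/√(r11·r22) is the quantity of
interest; coevolution is tested by a likelihood-ratio test against the
nested null r12 = 0, using the χ²(1) upper tail. BM is an adequate
approximation only for traits without strong stabilizing selection toward
an optimum; the independent-contrasts screen (below) filters genes whose
contrasts show scale-dependent variance, the standard symptom of
departures from BM.

Assumptions worth stating plainly: one species tree for all pairs (no
gene-tree discordance), conserved interactions across the clade, branch
lengths proportional to time, and measurement error independent across
species and traits.

## Fitting

θ enters the mean only, so it is profiled out exactly by generalized least
squares at each candidate R. R is parameterized as r11 = e^a, r22 = e^b,
ρ = tanh(z), which enforces positive definiteness; |z| is bounded at
atanh(1 − 10⁻⁶), so collinear data are clamped at |ρ̂| = 1 − 10⁻⁶ and
flagged as boundary fits (and retained). The null decouples into two
univariate BM fits solved by bounded scalar minimization of the profiled
likelihood in a. The full model is optimized by L-BFGS-B from three
deterministic starts z ∈ {−0.5, 0, 0.5} with (a, b) seeded at the null
optimum — which makes the full-model likelihood provably at least the
null's, so the LRT statistic is nonnegative up to floating-point noise
(floored at 0). Stalled line searches are polished with a Nelder-Mead
pass. Convergence tolerance is ~1e-10 on the objective; fits are
deterministic given the data.

Numerical notes: the 2n×2n covariance is factored by Cholesky each
evaluation (n ≤ ~100 is the intended regime); a singular covariance raises
with condition diagnostics; missing SEs are treated as 0 with a warning
(the supported path for unreplicated species is the proxy-SE rule).

## Normalization

Each replicate's TPM vector is mapped to the standard lognormal scale:
z = (ln TPM − mean)/sd over genes with TPM > 0, sample (n−1) sd. Zero TPM
has no log value and is treated as missing; genes missing in any species
(or any replicate of a species) are excluded, along with the pairs
containing them. Replicates are summarized to mean and SE = sd/√m; species
without replicates inherit SEs gene-wise from a designated closely-related
proxy species. Standardization is computed over all genes present in the
sample, not only the genes retained downstream. The time-course curation
helper selects the first 3 mutually correlated replicate columns at
Pearson r > 0.98.

## Independent contrasts and the BM screen

Contrasts are computed by Felsenstein pruning; multifurcations are resolved
deterministically (child order) with zero-length edges. The screen
correlates |standardized contrast| with contrast SD — the absolute-value
form of the classic diagnostic; the raw form is available via
`--bm-diagnostic raw` — and flags a gene when the Pearson p-value is below
0.05. The test is applied once per gene on the full species set; any pair
containing a flagged gene is dropped. Degenerate traits (zero variance in
either vector) are untestable and pass through unflagged.

## Group statistics

The weighted Spearman correlation ranks both variables (average ranks for
ties, unweighted) and applies weights w = ½(1/N₁ + 1/N₂) — N_i the number
of appearances of gene i within the analyzed set — only in the Pearson
step on ranks. CIs are percentile bootstrap over pairs (B = 2000, seeded),
with weights recomputed from appearance counts inside each resample; the
p-value is twice the smaller tail proportion of bootstrap estimates around
0, floored at 1/B. Group location is summarized by one-sample t-tests
against 0 with 95% CIs and a Welch t-test between groups. BH correction is
the standard step-up procedure, applied across all pairs tested in one run
(in the benchmark: per assessment repetition over the pooled
binding + control subsample). Membership-controlled resampling draws 200
seeded subsets in which each gene appears at most once, capped at 200
pairs.

## Empirical-null procedures

Crossover: histograms of binding and control correlations on shared edges
spanning [−1, 1], default bin width 0.05 (configurable; the original
description does not state one). The cutoff is the left edge of the
smallest nonempty bin from which the binding relative frequency strictly
exceeds the control's in every nonempty later bin; empty bins are skipped
to avoid spurious failures on sparse data; classification is inclusive
(r ≥ cutoff). A never-crossing pair of histograms yields a no-cutoff
sentinel and zero calls. In the benchmark the cutoff is learned on a
stratified 80% split and evaluated on the held-out 20%, re-split per
repetition.

Randomization: each pair's correlation is compared with 1000 draws (with
replacement) from the control pool, excluding control pairs that share a
gene with the target (leakage guard, toggleable); p = (k + 1)/(n + 1) with
k the count of strictly greater draws, so p never reaches 0. The p cutoff
is the largest observed p-value whose empirical FDR (control calls over
all calls) is at most the 5% target.

## Modularity

MCL runs on the dense column-stochastic matrix with self-loops of weight
1, expansion 2, inflation 2, pruning threshold 1e-5, convergence tolerance
1e-6, at most 100 iterations; STRING-style weights are divided by 1000
first. Attractor rows define clusters, overlaps merged by connected
components; the procedure is deterministic. The Covariance Ratio for
modules a, b is ‖S_ab‖_F / √(‖S_aa°‖_F‖S_bb°‖_F) (within-block diagonals
zeroed), averaged over module pairs of size ≥ 15; significance is the
add-one proportion of 999 trait-label permutations with CR at or below the
observed value (one-sided toward modularity; trait-label permutation was
chosen over row permutation as the scheme that leaves the trait covariance
itself intact). Before the test the species dimension is whitened with
C = U D Uᵀ: rows of D^{−1/2}Uᵀ(X − 1θ̂ᵀ) are exchangeable under BM.

## Synthetic data

The generator reproduces the study conditions: a Yule tree with 18 tips
rescaled to root age 723 My (the generator runs the process past the n-th
birth by one exponential waiting time so pendant branches are positive);
binding pairs with evolutionary correlation drawn from a truncated normal
(mean 0.45 — the fitted mean of the empirical binding group — sd 0.25,
support (−1, 1)); control pairs with correlation 0; per-trait rates
lognormal(0, 0.5); root states 0 (fits are location-invariant); 3
replicates per species with observation noise sd 0.1 on the trait scale.
Replicates are summarized to means and SEs through the same code path the
normalization stage uses. The cross-gene lognormal standardization itself
is exercised on TPM-scale input by the pipeline, not re-applied to
simulated traits, which are already on the normalized scale by
construction.

What the generator does *not* emulate: the real clade's tree shape (a
Yule tree spreads splits much more evenly than the actual fungal phylogeny,
whose recent *Saccharomyces* radiation packs many very short branches into
a 723-My-deep tree — tip correlations, and with them the anti-conservatism
of non-phylogenetic tests, are therefore weaker here); empirical rate
matrices (surrogate distributions replace rates fitted to real pairs);
shared genes across pairs (every simulated pair has its own two genes);
library-size and mapping artifacts of real RNA-seq. Passing benchmarks
consequently demonstrate correct method behavior under the BM model, not
performance guarantees on any particular empirical clade.

## Benchmark protocol

All pairs are fitted once; per assessment repetition the control set is
subsampled without replacement to the binding set's size and each method
is scored by TPR, FPR, FDR (0 when no calls) and accuracy against the
simulation labels; 20 repetitions are used in the scaled study (100 is the
default elsewhere). Method calls: PCM and Pearson at BH q < 0.05 pooled
within the repetition's subsample; crossover on the held-out 20%;
randomization at its FDR-calibrated cutoff. Problem sizes in the shipped
study: 500 binding + 500 control pairs, 18 tips — chosen as the smallest
scale at which the methods' orderings are stable across seeds.

## Known limitations

Two-trait rate matrices only (no Ornstein-Uhlenbeck alternative, no >2-gene
sets); one species tree for all pairs; the BM screen tests genes
marginally, not pairs jointly; bootstrap p-values are resolution-limited at
1/B; the crossover cutoff is sensitive to bin width on small samples.
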