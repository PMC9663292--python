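# Methods

## Synthetic cohort model

The generator produces the statistical structure the analysis layer
assumes, not realistic taxonomy. Per sample *s* and feature *f* the latent
natural-log absolute abundance is

    L_sf = alpha_f + I(case_s)·ln(2)·lfc_f + sigma_c·g_{s,c(f)} + eps_sf

with feature baselines `alpha_f ~ N(0, baseline_log_abundance_sd²)`
(default sd 2.0 ln-units, giving the several-orders-of-magnitude dynamic
range of species tables), planted signed log2 fold changes `lfc_f`
(default 20 features, magnitudes uniform on [1, 2], random sign), one
standard-normal latent factor per correlation cluster shared by its members
(default loading 0.8, chosen so within-cluster log-abundance correlation is
≈ 0.4 before counting noise), and i.i.d. residual noise `eps_sf`
(`sample_log_noise_sd`, default 1.0). The spec'd field list carries no
residual-noise term, but without one all samples of a group would be
identical up to cluster factors; the field is deliberate plumbing.

Counts are multinomial draws from `softmax(L_s)` at a log-normal per-sample
depth (default ln-mean `ln 3.6e7`, matching the post-QC read depth of large
shotgun studies, ln-sd 0.5). This latent log-normal → multinomial route
composes fold changes, cluster factors and sampling fractions additively on
the log scale, matching the additive log-scale models fitted downstream; a
Dirichlet-multinomial would not. Zeros arise only from the multinomial and
a detection limit (default 1e-5 relative abundance, the order of a
marker-based profiler's floor): below-limit entries are zeroed in both the
count and relative tables and the relative rows renormalized. Consequently
count rows sum to the drawn depth exactly only at `detection_limit=0`; with
a nonzero limit they sum to depth minus the zeroed mass — the two published
invariants (multinomial conservation and post-zeroing closure) cannot both
hold verbatim, and closure wins.

**Dominance cap on planted effects.** Planted fold changes are assigned
only to features whose expected baseline composition share is ≤
`differential_max_share` (default 0.5%). Fold changes are specified on the
relative scale; planting a 4-fold change on a composition-dominating taxon
would let closure both compress the planted effect and impose a spurious
shift on every null feature, making "the planted log2 FC" ill-defined. The
cap keeps the direct group-mean calibration property (planted effect
recovered within Monte-Carlo tolerance before any modeling) true by
construction. Real dysbioses involving dominant taxa are therefore outside
what the recovery tests certify.

The recorded true sampling fraction is `y_s = ln(depth_s) − ln Σ_f exp(L_sf)`,
mean-centered: the offset relating expected observed counts to latent
absolute abundances. Binary covariates are drawn per sample conditionally
on case status to hit a target odds ratio in expectation; the constipation
layer draws a flag whose log-odds vary linearly in centered log2 collapsed
abundance around group baselines (defaults 44% cases / 12% controls).

All draws come from one `numpy` Generator seeded by `config.seed`, in fixed
order (baselines, effects, clusters, depths, factors, noise, counts,
covariates), so identical configs give byte-identical tables.

What the generator does **not** emulate: phylogenetic covariance, realistic
rank-abundance shape beyond a log-normal, batch effects, compositional
interactions between planted effects and clusters, or zero inflation beyond
detection + sampling. Passing recovery tests therefore certify the
statistical machinery, not performance on real dysbiosis.

## Metadata contrasts

Fisher's exact test (two-sided, hypergeometric-sum definition) with the
conditional-MLE odds ratio and exact conditional CI; a zero cell switches
the OR to the Haldane-corrected sample OR with Woolf log-normal CI — this
matches the convention of reporting `fisher.test`-style ORs with a Woolf
fallback. Wilcoxon rank-sum is exact for ≤ 25 per group without ties,
normal approximation with tie correction otherwise. No multiplicity
correction: the screen's purpose is to flag any candidate confounder.

## Compositional tests

clr uses the +1 pseudocount on counts exactly as specified by the source
formula (not half-minimum). PERMANOVA is implemented through the
Gower-centered distance matrix (McArdle–Anderson), so no explicit embedding
is needed and the pseudo-F is exact for Euclidean distances; covariates are
partitioned sequentially before the group term and held fixed under
permutation. Permutation p-values use the (1+exceedances)/(1+permutations)
estimator — the smallest reportable p at 9,999 permutations is 1e-4 — and
`n_perm="exhaustive"` enumerates all distinct label arrangements (plain
proportion, identity included) for oracle comparisons at small n. PERMDISP
embeds the distance matrix by classical scaling, finds group spatial
medians by Weiszfeld iteration (tol 1e-8, max 1000 iterations, centroid
fallback with a warning), and permutes group labels recomputing medians
each time. The sequential chi-squared uses Pearson's statistic without
continuity correction at every step so per-category contributions
`(O−E)²/E` decompose it exactly; ties in contribution (within 1e-12) go to
the lexicographically first category.

## Differential abundance

The two models deliberately differ only in their abundance scale. The
relative-abundance model uses a per-feature pseudocount of half the
smallest nonzero relative abundance (the convention of log-linear
relative-abundance testing); the +1 pseudocount applies only to counts.
Quantitative covariates are z-scored before fitting; binary covariates
enter as 0/1; constant columns (e.g., a single collection kit) are dropped.
Coefficients, standard errors and two-sided p-values come from vectorized
OLS with the t reference at n − p degrees of freedom; fold-change CIs use
±1.96·se on the model's log scale. Features are tested marginally (both
reference methods are feature-wise).

The sampling-fraction estimator is alternating least squares on
`z = ln(count+1)`: group-wise feature means of `z − y`, then per-sample
feature means of `z − mu`, centering `y` each round, to convergence (max
|Δy| < 1e-6, ≤ 100 iterations). This replaces the published E-M bias
estimator of the bias-corrected method — the interface (the per-sample `y`
of the bias-correction formula) is what downstream code consumes, and the
estimator is validated by planted-offset recovery (correlation > 0.9 with
the generator's truth at 100 features). Group-structured means keep genuine
group effects out of `y`; a global compositional shift between groups is
*not* removed (see the dominance cap above).

BH FDR is the standard step-up (delegated to statsmodels, with a naive
quadratic oracle in the tests); NaN p-values propagate NaN q-values. The
consensus rule calls a feature at (q₁ < 0.05 and q₂ ≤ 0.1) or vice versa;
discordant coefficient signs demote the call with a warning. The confounder
rerun restricts to called features, drops samples listwise on all model
terms, re-applies BH over the restricted set, and reports per-covariate
direction symbols (++/−− at FDR < 0.05, +/− at FDR < 0.15).

## Networks

SparCC follows the original procedure: Dirichlet(counts+1) fractions per
iteration, log-ratio variance matrix, basis-variance linear solve under the
sparsity assumption, iterative exclusion of the most-correlated pair above
0.1 (up to 10 rounds), median over iterations (default 100), clipped to
[−1, 1]; non-positive basis variances mark a feature's correlations NaN.
The permutation null shuffles each feature's counts independently across
samples, preserving marginals while breaking dependence; p is the plain
proportion of random |r| ≥ observed |r| (ties count as exceedances), so
p-values sit on the 1/n_random grid with no positive floor. Inside the
permutation loop SparCC runs at reduced iterations (default 20 or fewer)
for tractability; the recovery properties are quoted at the reduced
setting. Networks are built per group (cases-only, controls-only) from all
detected features, capped at the most abundant features plus planted
cluster members when a cap is needed for runtime. Louvain runs unweighted
on the thresholded graph (negative-r edges included as plain edges, since
thresholding is on |r| and mixed-sign clusters are expected); |r| weighting
is exposed as an option.

## Grouped tests

Collapsing sums relative abundances before the log transform; the
pseudocount rule is inherited from the feature-wise model, so a singleton
collapse reproduces the feature-wise fit to 1e-10. Stratified constipation
tests drop (never impute) samples missing the flag, and skip a stratum with
no contrast with a warning.

## Problem sizes and numerical choices

Defaults throughout were chosen as the package's own desk-scale study
conditions: cohorts of 200/200 with 257 features and 20 planted effects for
recovery (50 seeds) and null calibration; PERMANOVA/PERMDISP type-I error
at 200 replicates of n=30 with 99 permutations (nominal 5% is exactly
achievable on that p-grid); network recovery with 3 planted 8-feature
clusters among 40 features at n=200 samples, 200 random datasets.
Tolerances: clr centering and closure at 1e-9; exact-oracle agreement at
1e-12; Weiszfeld at 1e-8; sampling-fraction convergence at 1e-6.

## Known limitations

The bias-corrected model shares the relative-abundance model's
vulnerability to large group-level compositional shifts. SparCC's sparsity
assumption fails for densely correlated panels (many features in few large
clusters). PERMDISP's permutation scheme (raw label permutation with median
recomputation) is slightly conservative relative to residual-permutation
variants. The enterotype classifier itself is out of scope — labels are
inputs or synthesized.
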