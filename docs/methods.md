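# Methods

## Effect sizes

Hedges' g is computed as g = J·(x̄_T − x̄_C)/s_p with the pooled standard
deviation over both groups and the small-sample correction in its standard
approximate form J = 1 − 3/(4m − 1), m = n_T + n_C − 2, rather than the
exact gamma-function ratio; for the m = 6 typical of 4-vs-4 designs the two
differ by ~1e-3, well below the sampling noise of g, and the approximation
is the conventional form in ecological meta-analysis. The variance uses the
standard large-sample expression (n_T+n_C)/(n_T·n_C) + g²/(2(n_T+n_C)).
Confidence intervals use the normal quantile 1.96 throughout (not a t
quantile), because the downstream index sums many variables and its CI rests
on a normal approximation to a variance-propagated sum anyway; using the
same quantile at both levels keeps the two displays consistent.

The sign convention is treated minus control. Two degenerate cases are
handled explicitly: both groups constant and equal → g = 0 with the
sample-size variance term only (a well-defined "no effect" statement);
constant but unequal → an error, since the standardized difference is
undefined. Which variables are log10-transformed before computing g is
configuration, not inference — typical practice log-transforms gene-copy
abundances and leaves rates, pools and diversity indices untransformed, and
that is how the default synthetic design is set up.

## The aggregated impact index

EAI = Σ|g_v| over the configured variable set; var(EAI) = Σ var(g_v). The
variance of the sum is taken as the sum of the per-variable variances — the
absolute value is *not* propagated through a folded-normal correction —
because that is the published form of the index; it is slightly
conservative (the folded-normal variance is never larger). A
`folded_variance=True` option exposes the alternative for sensitivity
analysis, off by default.

Because |g| has positive expectation, EAI is strictly positive in
expectation even when every true effect is zero (≈ 14.7 for 26 variables at
n = 4 + 4); EAI values are therefore only interpretable relative to each
other, never against zero, and the letter display encodes exactly those
relative comparisons.

Significance between treatments is read from 95% CI overlap on closed
intervals (touching endpoints count as overlapping — the conservative
reading). The compact letter display is built by a sweep that exploits the
Helly property of intervals on a line: every maximal clique of the overlap
graph is the set of intervals covering some interval's lower bound, so
collecting those cover-sets and absorbing subsets yields the maximal
cliques, which become the letters. Any algorithm producing a valid display
would do — the tested contract is the relation (shared letter ⇔ overlap),
not the particular labels. Letters are assigned within each timepoint by
default, since impact trajectories are compared between treatments at a
common time; a flag switches to lettering across all cells.

## Community metrics

Dataset-wide singletons (OTUs with total count 1 across all samples) are
removed before rarefaction; rarefaction draws each sample down to the
configured depth (2200 by default) in a single multivariate-hypergeometric
draw per sample — exact subsampling without replacement, no averaging over
repeated draws. Alpha diversity: observed species, Simpson's reciprocal in
the plug-in form 1/Σp² (k equally abundant taxa give exactly k; the
bias-corrected n(n−1) form is deliberately not used, matching common
pipeline defaults), and Faith's PD in the root-inclusive convention (the
minimal subtree always contains the root). Weighted UniFrac defaults to the
raw, non-normalized form with the normalized variant behind a flag;
unweighted UniFrac is normalized by construction. Faith's PD and UniFrac
are computed by scikit-bio, whose conventions match these definitions; the
test suite cross-checks them against naive branch-enumeration oracles on
random trees.

PCoA double-centres −D²/2 and eigendecomposes with a symmetric solver.
Negative eigenvalues (non-Euclidean distances) are reported in the returned
spectrum but their axes are dropped from the coordinates; no
Cailliez/Lingoes correction is applied. Axis signs — arbitrary in any
eigendecomposition — are fixed by making each axis's largest-magnitude
loading positive, so outputs are reproducible across runs and platforms.

## Inference

One-way ANOVA is the fixed-effects F test per timepoint; a zero
within-group mean square with between-group variation present is reported
as an infinite F with p = 0 rather than NaN. Tukey HSD uses the
Tukey–Kramer studentized-range statistic q = |x̄_i − x̄_j| /
√(MS_w/2·(1/n_i + 1/n_j)) with p from the studentized range distribution
on (k, df_residual).

PERMANOVA follows the standard pseudo-F on squared distances, with
SS_total = Σ_{i<j} d²_ij/N and SS_within summed per group. The p-value uses
the Monte-Carlo convention (b + 1)/(m + 1) under free permutation of the
raw labels, with 999 permutations by default; an exhaustive mode enumerates
every distinct labelling for small N (used for exact tests). Note a
practical floor at very small groups: with 4 + 4 samples only 70 distinct
partitions exist, and free label permutation regenerates the observed
partition with probability 2/70, so with few permutations the attainable
p is bounded away from small values — one reason the default is 999.
Pairwise PERMANOVA runs the test on each unordered pair's samples;
Benjamini–Hochberg adjustment is available but off by default (pairwise
outcomes are reported raw).

Variance partitioning is the sequential (Type-I) decomposition: terms enter
a least-squares model in the configured order, each single-df numeric term
is charged the reduction in residual SS when it enters, F is taken against
the residual MS of the full model, and percentages are of total SS (terms
plus residual sum to 100). Term order is consequential and is part of the
configuration, not inferred. In the pipeline, the observational unit is one
(treatment, timepoint) cell: the response is that cell's EAI and each
predictor is the cell's shift summary — the mean rarefied-community
distance from the cell's samples to same-timepoint control samples for
distance metrics, or |g| of a named variable otherwise.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes, not
the biology. Measurements: control replicates are i.i.d. Normal(μ_v, σ_v);
treated replicates are Normal(μ_v + δ·σ_v, σ_v) with δ the planted
standardized effect per (treatment, timepoint, variable). Variables flagged
for log10 analysis are drawn on the log scale and written back as 10^x, so
the analysis-side transform exactly recovers the planted δ. The default
design mirrors a compounded-disturbance study: a control, three repeated
single disturbances (F, H, A), the six chronology orderings (FHA … AHF),
4 replicates, timepoints T0–T4, and 26 variables spanning process rates,
N pools, log-scale gene-copy abundances and diversity indices.

Communities: counts are Dirichlet-multinomial. Base alphas are
lognormal(0, 1.5) normalized to a total concentration of 50 (strong
overdispersion, of the order seen between soil amplicon replicates); a
disturbance multiplies the alphas of a randomly chosen fraction of OTUs
(default 30%) by e^shift, with the affected set shared by a cell's
replicates. Sequencing depth is uniform on (2500, 5000), above the 2200
rarefaction depth. The phylogeny is a random bifurcating rooted tree from
successive random joins with Exponential(mean 0.1) branch lengths.

What the generator does *not* emulate: temporal autocorrelation within a
microcosm (timepoints are independent draws), variable–variable
correlation (effects are planted independently per variable), taxon-level
disturbance ecology (affected OTUs are random, not trait-structured), and
sequencing error. Passing tests therefore demonstrate the statistical
machinery under its own assumptions — normality on the analysis scale,
exchangeable replicates — not robustness to real-data violations of them.

The bundled "study-like" scenario plants per-treatment effect scales
ramping over time (zero at T0) and spanning weak to strong aggregated
impacts across the nine treatments, and couples the community shift to the
same per-cell scale (log-fold 1.0 × scale on 30% of OTUs) with a scenario
concentration of 400 so that composition change tracks functional change —
mirroring the qualitative behaviour such experiments show, where strongly
impacted microcosms are also compositionally shifted (detectable by
pairwise PERMANOVA) and community distance explains a large share of EAI
variance. With the default concentration of 50, per-replicate compositional
noise dominates plausible shifts and the distance predictor is
uninformative; both regimes are legitimate, and the scenario deliberately
uses the informative one.

## Problem sizes and numerical choices

The test suite and acceptance script use: 2000 simulated experiments for
effect-size recovery and the EAI null (sampling SE of the null mean ≈ 0.06,
ample for a 5% relative check against the Monte-Carlo oracle); 500 random
interval sets for the letter display; 200 random ≤8-leaf trees for the
tree-metric oracles; 1000 draws for the hypergeometric rarefaction check;
1000 structureless simulations at 199 permutations for PERMANOVA
calibration; and 100 repetitions for EAI-ordering recovery. The ordering
scenario uses six chronology treatments with per-variable δ = 1.5·rank and
16 replicates: at n = 4 the CI half-width grows with δ faster than the
between-treatment spacing, so no δ scaling can satisfy the "adjacent
aggregates ≥ 3 half-widths apart" design condition — raising replication is
the lever that does, and the test verifies the spacing condition before
scoring recovery.

Ties in permutation tests are counted as exceedances (F_perm ≥ F_obs − 1e-12)
to keep p-values valid; PCoA treats eigenvalues below 1e-10 of the leading
one as null axes; report tables round to 6 significant digits, which
round-trips the plotted quantities losslessly.

## Known limitations

- The EAI variance ignores correlation between variables measured on the
  same microcosms; positively correlated responses make the stated CI
  anti-conservative. The published form is reproduced deliberately.
- CI-overlap letterings are more conservative than pairwise tests at the
  same nominal level; non-overlap at 95% corresponds to a stricter
  criterion than p < 0.05.
- Type-I partitioning charges shared variance to whichever term enters
  first; reported percentages are order-dependent by construction.
- PERMANOVA p-values at n = 4 per group have a resolution floor set by the
  70 distinct partitions, regardless of permutation count.
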