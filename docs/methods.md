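# Methods

## Features: introns and bunches

Junctions are extracted from spliced alignments by scanning CIGAR `N`
operations. An intron is stored 1-based inclusive over the skipped bases:
for a read starting at position 1 with CIGAR `10M100N10M`, the intron is
bases 11–110. A read supports a junction only if both flanking exonic
anchors carry at least `min_anchor` matched bases (default 8); junctions
below `min_count` total reads (default 1) are dropped. Strand comes from
the `XS` tag when present, otherwise `?`; introns differing only in known
strand are kept distinct, while `?` is compatible with either strand for
grouping.

Bunches are connected components of the graph linking introns on the same
chromosome (strand-compatible) that share a start or an end coordinate.
Connectivity is transitive, so a bunch can contain introns with no direct
shared site; transitive closure is the only grouping that partitions the
intron set. Bunches of size 1 cannot carry a splicing ratio and are
excluded from DSR.

## Design encoding

Numeric covariates are centered and scaled with the population standard
deviation (divisor N); a constant covariate encodes as zeros with a
warning. Categorical covariates are integer-coded 0..K−1 in sorted level
order — a deliberate single-column ordinal encoding; for a covariate this
matches the intended linear-effect model, and two-level factors (the
common case: sex) are unaffected by the choice. The condition variable is
expanded into K−1 indicator columns against the first sorted level, so
every non-reference condition has its own coefficient and multi-way
comparisons test all conditions jointly. Missing covariate values are an
error, never imputed: silent imputation would bias exactly the adjustment
the tool exists to perform.

## DSA: zero-inflated negative binomial regression

Per intron, counts are zero with probability π (one π per intron, shared
across samples) or NB with mean `exp(c + x·b + log s)` and dispersion θ
(variance m + m²/θ). The log link keeps means positive for any covariate
value and matches the softmax link of the ratio model. `s` is a
median-of-ratios size factor (computed over introns detected in all
samples; total-count fallback below 10 such introns) normalizing library
depth; without it, a chance depth imbalance between groups is
indistinguishable from a global condition effect.

Fitting is MAP via L-BFGS-B with analytic gradients on the unconstrained
parameters (intercept, coefficients, log θ, logit π), with box bounds to
keep the objective finite (|logit π| ≤ 12, log θ ∈ [−8, 10]). Priors,
implemented as unnormalized log-penalties so that the alternative
objective at the null solution equals the null objective exactly
(guaranteeing nesting):

* pooled baseline mean `B = exp(c + x̄·b)` ~ N(μ̂, sd √μ̂), μ̂ = mean of the
  intron's nonzero counts. Penalizing the pooled baseline rather than the
  raw intercept matters: the intercept of the alternative model is a
  group mean, and penalizing its deviation from the pooled μ̂ shrinks the
  condition contrast asymmetrically (measured as null type-I error
  dropping to 0.01–0.03 from the nominal 0.05);
* inverse dispersion θ⁻¹ ~ √HalfCauchy(0, 1), discouraging degenerate
  near-Poisson fits;
* a weak N(0, 25) ridge on regression coefficients, purely for stability
  when a condition group is all zeros.

The optimizer starts from moment estimates (and, for the alternative,
from the null solution padded with zero condition coefficients, which
enforces nesting in practice); up to two seeded random restarts run only
when a fit fails to converge. The likelihood-ratio statistic
2(L₁ − L₀) (penalized objectives) is clipped at zero and referred to a
χ² whose degrees of freedom are counted mechanically as the difference in
free parameters. An intron is testable when every condition has at least
2 samples with a nonzero count.

## DSR: Dirichlet-multinomial regression

Per bunch, y_i | n_i ~ DM(n_i, α p_i) with p_im the softmax of
`x_i β_m + a_m` and the last intron fixed as reference (β_M = a_M = 0) —
softmax shift-invariance makes one reference necessary and sufficient for
identifiability. α is a single bunch-level concentration: the minimal
overdispersion model consistent with the concentration-times-proportion
parameterization; per-intron or per-sample concentrations would be weakly
identified at typical sample sizes. The log-pmf is computed directly via
`gammaln` (per-sample concentration vectors, vectorized over samples);
`scipy.stats.dirichlet_multinomial` serves as an independent cross-check
in the tests.

Priors: weak N(0, 5) on intercepts and coefficients, and
α⁻¹ ~ √HalfCauchy(0, 1) — the same family as the DSA dispersion prior.
The concentration prior is load-bearing: maximum likelihood overestimates
α at N ≈ 20–40 (underestimates overdispersion), inflating the null LRT by
10–25% and the type-I error to 0.07–0.10; with the prior the null
distribution of p-values is uniform within Monte-Carlo error. A bunch is
testable when M ≥ 2 and at least 2 samples per condition have a bunch
total ≥ 5 (low totals make proportions uninformative). Per-condition PSI
averages the fitted p_im over the condition's samples; dPSI is the
maximum absolute fitted-PSI difference over introns and condition pairs.

## Covariate-adjusted counts and PSI

Residuals are per-feature, per-sample 1-D MAP problems with the fitted
alternative-model parameters frozen and prior r ~ N(0, variance 10,
configurable). For abundance, r_i maximizes the ZINB likelihood of y_i
with mean `exp(c + x_i·b + log s_i + r)`; a zero count with fitted π > 0.5
is attributed to the zero component and keeps the prior mode r = 0
(flagged). Adjusted counts are `exp(c + x̃_i·b + r_i)` with covariate
columns zeroed (all non-condition columns by default), reported both
real-valued and rounded.

For ratios, the printed adjustment adds one scalar r_i to every intron's
logit — which cancels in the softmax, so its MAP value is the prior mode
and adjusted PSI is the softmax of the covariate-zeroed logits,
deterministic within a condition. Because a per-sample scatter is what
makes adjusted-PSI PCA informative, an optional per-intron residual
vector r_im (independent N(0, 10) priors, MAP per sample) is available
(`per_intron=True`); it pulls adjusted PSI toward each sample's observed
proportions while still removing the covariate term, and is what the
PCA-based checks use.

## Synthetic benchmark generator

The generator emulates a spliced-read count benchmark at the
intron-count level: each gene is one bunch whose introns proxy its
isoforms (2–4 per gene, uniform). Counts arise hierarchically per sample:
a NB gene total (θ = 10) around gene mean × library factor
(log-normal, sd 0.2), split multinomially with per-sample proportions
drawn from a Dirichlet (concentration 60) around the gene's isoform mix —
correlated isoform counts and biological PSI variability, the structure
junction reads actually have. Gene expression is log-normal
(median 150 junction reads, sd 0.7); isoform mixes are normalized
log-normal levels (sd 1.0, sorted), giving the skewed dominant-isoform
profiles of real transcriptomes. Per-intron technical dropout is
available (`zero_inflation`) but defaults to 0: zeros then arise from
sampling alone, as in a bulk benchmark. With dropout enabled the DM
family is misspecified and DSR p-values become anti-conservative
(~2× type-I at 2% dropout) — a known limitation worth remembering with
sparse single-cell-like data.

Effects follow the benchmark design: differential expression halves or
doubles (Bernoulli(0.5), seeded) all isoform means in the affected group;
differential splicing swaps the two largest isoform means. Condition
effects key on the condition label, covariate effects on the covariate
level, at disjoint gene sets, so an imbalanced covariate layout
((8M, 2F) control vs (8F, 2M) disease) confounds the two. Defaults:
2000 genes; 200 genes each for condition DE, DS and DE+DS; 100 each for
the sex-keyed categories; 10 samples per condition×sex cell when no
imbalance is requested. The three-way layout keeps the disease change in
stage2 for half of each category, reverts the other half, and adds 200
new genes per category changed only in stage2 — yielding the 800-gene
ratio target and 1200-gene abundance target. Evaluation is gene-level:
Sn = TP/(TP+FN), Pr = TP/(TP+FP), F = 2·Sn·Pr/(Sn+Pr), with false
positives split into covariate-related (in the covariate-modified set)
and extrinsic.

What passing these simulations does *not* show: robustness to alignment
artifacts, annotation-dependent junction discovery biases, non-linear or
interacting covariate effects, and isoform structures more complex than
one bunch per gene.

## Visualization

All plots read one unified TSV (one row per intron, per-sample raw and
adjusted value columns, p/q/dPSI metadata). PCA centers features without
scaling (PSI is already bounded; scaling available via a flag), imputes
missing values with the feature mean, and drops features with more than
20% missing. Heatmaps use `scipy` hierarchical clustering, default
`weighted` linkage with the `cityblock` metric. Every plot also writes
its numeric backing table (PC coordinates, dendrogram leaf orders, Venn
region sizes), so results are checkable without parsing images.

## Problem sizes and determinism

Default study sizes — 2000-gene benchmarks, 500-feature null
calibrations, 10-replicate PCA checks — run in a few minutes on one CPU;
per-feature fits are independent and scale linearly. All randomness flows
from explicit integer seeds: a fixed seed makes simulation, fitting and
file outputs byte-reproducible; PCA coordinates are reproducible up to
per-component sign.
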