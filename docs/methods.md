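# Methods

## Design and model

The pipeline targets single-channel oligonucleotide arrays hybridized to a
tissue × block design: T whorl tissues (5: SEP, PET, STA, STD, CAR; or 4
without staminodia) × P replicate blocks ("populations"), one array per
cell. The per-gene model behind the contrast engine is a block-shift
linear model: the expression of gene g on the array for tissue t in block
p is

    y_gtp = α_g + β_g·[t ∈ G_c] + b_gp + ε_gtp

for a contrast c with whorl group G_c, where b_gp is a block (population)
random effect and ε is residual noise. With exactly one array per
tissue × block, the within-block difference
d_p = mean_{t∈G_c}(y) − mean_{t∉G_c}(y) eliminates b_gp exactly, and the
estimator

    coefficient = mean_p d_p,    se = sd_p(d_p)/√P   (sample sd, P−1)

is the generalized-least-squares solution under this model. We chose this
closed-form paired analysis over an iterative REML mixed-model fit: it is
exact for the design at hand, deterministic, and fast enough to repeat
over every permutation. P ≥ 2 is required; the fit refuses designs where
a block lacks group or complement arrays.

## D statistics and significance

D = coefficient/(se + s0) with s0 the median se over genes for that
contrast (floored at 1e-9 so zero-variance toys stay finite). s0 is
computed once from the observed data and reused for all permutations of
that contrast, keeping the permuted statistics on the observed scale.

Significance is SAM-style. Tissue labels are shuffled over all arrays
(n_perm = 99 by default; block labels stay attached to arrays). An
unconstrained shuffle can leave a block with no group (or no complement)
arrays for some contrast; such blocks are dropped from that contrast's
fit when at least two remain, otherwise the permutation is redrawn. A
`within_blocks` option restricts shuffling to blocks, which keeps every
permutation balanced; a `resample="bootstrap"` option draws labels with
replacement. Ranked permuted D values are averaged rank-wise to give the
expected ranked D; a gene at ascending rank i is called when
observed(i) − expected(i) exceeds delta (default 4) upward or downward.
The FDR estimate is the median over permutations of the number of
permuted D values at or beyond the call cutoffs, divided by the number of
calls, capped at 1 (the raw ratio can exceed 1 under the null; no π0
correction is applied). Organ specificity assigns each gene the contrast
with maximal |D|, ties broken toward the lowest contrast id, direction by
the sign of D there.

Complementary contrasts (e.g. the A domain SEP+PET and its complement
STA+STD+CAR in the five-whorl set) are exact mirrors of one another:
coefficients and D negate bit-for-bit, standard errors and s0 coincide.
This is asserted as an invariant, not approximated.

## Preprocessing chain

Fixed order, recorded in provenance and enforced (running a stage out of
order raises): log2 with an intensity floor of 1.0 (scanner-floor
convention) → spatial correction → quantile normalization → probe
centering → gene summarization (genes with < 4 probes dropped and
reported).

Spatial correction is deliberately parameter-light: per array, residuals
from the array median are smoothed with an edge-truncated window×window
moving median over the probe grid (default window 15) and subtracted; the
array median is restored exactly afterwards. On a smooth low-frequency
surface (the artifact class the generator plants) a 9-cell window removes
≈ 95 % of the artifact variance at the grid sizes we simulate. On a
noiseless linear ramp the interior is flattened exactly; note that a rank
correlation of the corrected values against the gradient axis is not a
meaningful diagnostic there, because the flattened interior is one large
tie block — the test suite therefore checks interior flatness exactly and
the rank correlation only on a noisy gradient.

Quantile normalization follows Bolstad: each array's order statistics are
replaced by the across-array mean order statistics; tied values receive
the mean of the reference quantiles their ranks span. Two consequences of
the tie rule are documented rather than hidden: (i) idempotence is exact
only on tie-free data; (ii) normalization is exactly transparent to a
planted effect only when all arrays share the same value distribution.
The zero-noise exactness test plants equal-sized effects on a contrast
and its complement with a fixed probe count, which makes every array's
distribution identical and the whole chain exact to < 1e-9; with
one-sided planting, quantile normalization necessarily shrinks the
planted difference (for a flat background the surviving fraction is the
planted group's share of arrays). This is a property of quantile
normalization itself, not of this implementation.

## Enrichment

PAGE: z = (S_m − μ)·√m/σ, with μ and σ the mean and population
(denominator N) standard deviation of the D statistics over the universe
— the genes that both carry a D statistic and have at least one
annotation surviving the filters. Categories are intersected with the
universe before the ≥ 10 size filter. Two-sided normal p values are
Benjamini–Hochberg adjusted within each contrast's family of categories
(per-contrast families match how per-contrast result lists are reported;
a pooled family would be an easy switch). Annotations are used as given;
no GO-graph ancestor propagation is performed.

## Homology and correlation

Reciprocal pairing filters each directional hit table at its inclusive
E-value threshold (≤, defaults 5e-6 forward and 7e-6 reverse), takes the
best hit per query (lowest E, ties by higher bit score then lexicographic
subject id) and keeps mutually-best pairs, guaranteeing a one-to-one
pairing. An `any-intersection` mode implements the looser "hit in both
directions" rule. Spearman correlations use average ranks with p from the
t approximation on n−2 df (adequate for n ≥ 50; cells with fewer than 3
usable pairs, or a constant statistic, are reported missing). Per-whorl
correlation defaults to the whorl-specific contrast D values; a
gene-centered mean-expression mode is provided.

## Synthetic data

The generator mirrors the analysis model: gene baselines
N(baseline_mean = 8, gene_sd = 1), probe affinities N(0, 0.5), per
(gene, block) random effects N(0, 0.25), residual noise N(0, 0.25), all
log2; a per-array spatial surface (sum of two 2-D cosines, frequencies
1–2 across the grid, random phases, amplitude 0.3) and planted gene-level
effects applied to every array whose tissue lies in the planted
contrast's group. Raw intensities are 2^log2. Probes are placed on
random distinct grid cells; 3–35 probes per gene by default. Everything
is a pure function of (params, seed).

What the generator does **not** emulate: cross-hybridization, intensity-
dependent (nonlinear) probe response, background/saturation, dye or
scanner physics, correlated gene programs beyond the planted contrasts,
and annotation structure (GO hierarchy). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data pathologies.

Companion generators plant enriched GO categories (members drawn from
genes planted on a chosen contrast) and homolog hit tables whose
reciprocal-best-hit set equals the planted pairs by construction: true
pairs receive mutually-best E ≤ 1e-8 in both directions, decoys lie in
[10^-7.5, 10^-5] (strictly worse), and reverse-direction decoys are only
issued from queries that already have a true partner, so no spurious
reciprocal pair can form.

## Calibration and problem sizes

The null-calibration studies run 200 simulated studies of 2,000 genes ×
15 arrays with 4–8 probes per gene, spatial window 9 and 99 permutations
— sizes chosen so the full probe-level chain (not a shortcut) is
exercised in a few minutes on one CPU. Under the global null every call
is a false positive, so the realized false-positive proportion is
identically 1; the check is that the estimated FDR at the smallest delta
yielding ≥ 5 calls tracks it (band frozen from a 20-seed pilot: mean
within 0.05 of 1, ≥ 95 % of seeds ≥ 0.9). The PAGE null check counts raw
p < 0.01 over random categories (40 per seed, sizes 10–30, 12 contrasts,
100 seeds) against 0.01 ± 3 binomial SE. Signal recovery plants 50 genes
at 2.0 log2 (noise 0.25) and requires ≥ 90 % recovery at the smallest
delta with estimated FDR ≤ 0.05 and realized FDR ≤ 0.10; planted genes
are drawn with ≥ 4 probes since 3-probe genes are (by design) removed by
the summarization filter.

## Numerical choices

- Intensity floor 1.0 before log2.
- s0 floor 1e-9; FDR capped at 1; FDR 0 when nothing is called.
- Quantile-normalization ties: mean of spanned reference quantiles.
- Specificity ties: lowest contrast id (deterministic).
- Spatial window must be odd and ≥ 3; moving median is edge-truncated and
  ignores empty grid cells; computed in row blocks to bound memory.
- Per-stage seeds derive from the global seed via
  `SeedSequence([seed, stage_index])`, so isolated stage reruns reproduce
  the orchestrated run.

## Known limitations

- The FDR estimator inherits SAM's behavior of being conservative when
  many genes are differential (no π0 estimate).
- Unconstrained permutations with dropped blocks give permuted statistics
  with occasionally fewer effective blocks than the observed fit (se on
  2 rather than 3 blocks); `within_blocks=True` avoids this at the cost
  of a smaller permutation space.
- The PAGE normal approximation is trusted for category sizes ≥ 10; very
  heavy-tailed D distributions at tiny block counts make the approximation
  rougher for small categories.
- Printed per-contrast D values from other parameterizations of the
  group-difference model are not expected to be reproduced numerically by
  this symmetric parameterization; the argmax (specificity) structure is.
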