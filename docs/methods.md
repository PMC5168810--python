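# Methods

## Detection model

A two-condition dataset is a matrix G of M features by N samples with a
binary condition label per sample. Detection is a two-layer mapping:
first K "basic attributes" — per-feature test statistics s⁽¹⁾…s⁽ᴷ⁾, each
oriented so larger means stronger evidence of up-regulation in group 2 —
then a discriminant f(s) = Σ wₖ s⁽ᵏ⁾ − τ with Σ|wₖ| = 1. Feature i is
called when f(sᵢ) > 0 strictly. Up- and down-regulation use separate
discriminants with wₖ ≥ 0 and wₖ ≤ 0 respectively; the L1 constraint plus
sign constraints makes the weight simplex compact and favors sparse
boundaries. The learning objective is to maximize calls subject to an
estimated FDR below a user bound Ψ.

## FDR estimator

For fixed f, with dᵢ the original discriminant values and d*ᵢ,b the values
recomputed on B group-size-preserving label permutations:

* P(D_f > 0 | NULL) is estimated by Ê_b(#{d*ᵢ,b > 0})/M, with Ê_b the
  median over permutations (mean available via `e_b_mode`). The median is
  robust to the occasional permutation that accidentally aligns with
  signal.
* P(NULL) (the null fraction π₀) is estimated by #{dᵢ ≤ d_λ}/((1−λ)M),
  truncated at 1, where d_λ is the λ-quantile (lower interpolation) of the
  pooled permutation values and λ = 0.5.
* P(D_f > 0 | R > 0) is (r ∨ 1)/M with r = #{dᵢ > 0}; the ∨1 guard makes
  the estimate 0 when nothing is called and the permutation exceedance
  expectation is 0.

The product/quotient of the three gives FDR̂_λ, clipped to [0, 1] for
reporting. Permutation statistics are always recomputed by re-running the
full attribute pipeline on the relabeled data (voom weights, SAM fudge
factor, NB dispersions refit per permutation), never by shuffling the
original statistic vector — the joint null of the K attributes is what the
boundary search probes.

Numerical conventions: calls use strict dᵢ > 0; the π₀ numerator uses
dᵢ ≤ d_λ; a vacuous π₀ numerator (no value at or below d_λ) is floored at
one count so a degenerate quantile cannot certify FDR = 0. The quantile
ambiguity ("the value smaller than the λ percentile") is resolved as the
lower-interpolation quantile.

## Search algorithm

Weight vectors are enumerated on the simplex lattice at step δ
(C(1/δ+K−1, K−1) points; default δ = 0.05 for K ≤ 3, else 0.1 — 231 points
at K = 3 keeps the search cheaper than attribute extraction). For each
candidate w the data and permutation matrices are projected once; because
the π₀ numerator #{u ≤ q_λ} is invariant to τ (both sides shift together),
tuning τ reduces to scanning the sorted distinct projected values with
cumulative counts and per-permutation `searchsorted` exceedance counts.
All candidate cutoffs are evaluated — FDR̂ is not monotone in τ, so no
unimodality is assumed — and the feasible cutoff maximizing r wins, ties
going to the larger (more conservative) τ. Candidates with r = 0 are
treated as infeasible: r = 0 always has FDR̂ = 0 by the ∨1 guard, and
admitting it would make every weight vector trivially "feasible".

Grid ties are broken deterministically: larger r, then smaller
search-phase FDR̂, then fewer nonzero weights, then lexicographically
smallest w. The winning w is then recalibrated — τ re-tuned only — on an
independent permutation set drawn from a disjoint seed stream, and the
final calls and reported FDR̂ come from the recalibrated boundary. This
two-set scheme removes the optimism of selecting and certifying on the
same permutations. In "both" mode the up and down boundaries are fitted
and reported separately (no union-FDR certificate is constructed; the
per-direction estimates each satisfy Ψ). A feature above both boundaries
(possible only in pathological geometries) keeps the direction with the
larger margin. Defaults B = 100 search and B_cal = 500 calibration
permutations; when C(N, n₂) − 1 ≤ B every distinct non-identity
relabeling is used (exhaustive mode). In such small-N regimes the search
and calibration sets necessarily overlap as label-vector sets — there are
only C(N, n₂) − 1 distinct ones — so independence holds only through the
disjoint seed streams.

## Basic attributes

All extractors are deliberately self-contained functional equivalents of
the familiar designs; numerical equality with limma/voom/DESeq2/samr is a
non-goal.

* `sam_t` — (mean₂ − mean₁)/(s_g + s₀) with pooled-SD standard error s_g
  and a data-wide fudge constant s₀, default the median of the s_g (a
  quantile or fixed value is configurable). Zero-variance features with
  s₀ = 0 get statistic 0 (flagged) rather than ±∞.
* `sam_ranksum` — centered rank-sum W − n₂(N+1)/2 with mid-ranks for ties.
* `moderated_t` — two-group t with the residual variance replaced by the
  posterior (d₀s₀² + d_g s_g²)/(d₀ + d_g); the prior (d₀, s₀²) is
  moment-matched on log variances via digamma/trigamma equations
  (Newton-inverted trigamma), d₀ capped at 10⁶ to represent infinity.
  Accepts per-observation precision weights.
* `voom_t` — log₂ CPM with half-count offset, lowess trend of residual
  √SD versus average log-count (lowess `delta` = 1% of the x-range for
  speed), per-observation weights (predicted √SD)⁻⁴ interpolated at the
  fitted log-count with end-clamping, fed to `moderated_t`. Below 50
  features the trend is unreliable: unit weights with a warning.
* `nb_wald` — per-feature NB log-link GLM with group indicator and
  median-of-ratios size-factor offsets (factors rescaled to geometric
  mean 1). Dispersion: per-feature MLE by golden-section search on log α
  with group means profiled at a method-of-moments start, then shrunk on
  the log scale with weight 0.5 toward an a + b/mean trend fitted by
  least squares on the informative (non-boundary) dispersions. The Wald
  statistic is (η₂ − η₁)/SE with the SE from the observed information
  Σ μ(1+αy)/(1+αμ)²; all-zero features get 0 (flagged), non-convergent
  fits fall back to Poisson (flagged).

`sam_t`, `sam_ranksum` and `moderated_t` accept continuous data directly;
the count-based extractors require integer values and refuse continuous
input unless pre-scaled (`--scale-round 1000` multiplies and rounds, the
usual treatment of methylation fractions).

## Simulator

Each gene has a generating family: NB(mean, dispersion) or a 1–3 component
Gaussian mixture truncated at zero and rounded. Fitting to a reference
matrix: genes with counts below 10 in more than half the samples are
dropped; NB by MLE (dispersion clamped to 0 when variance ≤ mean); GMM by
EM with 5 restarts and BIC selection over k = 1..3 (SDs floored at 10⁻³ of
the data range); the family whose fitted distribution better correlates
with the gene's 20-equal-width-bin histogram wins, ties to NB. The
histogram criterion is a deliberately rough model-choice device — it
demonstrates distributional heterogeneity rather than performing rigorous
selection.

The download-free synthetic library emulates the mixture observed in deep
real data: 63.5% GMM / 36.5% NB, GMM component counts 44:50:6, expression
scales log-uniform over 10–10⁴, NB dispersions log-uniform over 0.01–1,
GMM component CVs 0.1–0.45 with Dirichlet(2) weights and log-normal
(σ = 0.55) spread of component means. These shape parameters are the
package's one free choice; they produce count matrices whose attribute
nulls behave like filtered bulk RNA-seq.

Null genes are redrawn until |log₂ FC| between the predetermined halves is
≤ 4.5 σ_N, where σ_N is the SD of log₂ fold-changes between random
disjoint N/2-sample groups of a reference matrix (pooled over genes and
1000 draws; log base 2 and pseudo-count 0.5 on group means are field
conventions the original recipe leaves open). In synthetic mode the
reference is a 40-sample matrix drawn from the library itself. True DEFs
are spiked by scaling one uniformly chosen group by U(1.5, 3.0) —
multiplied or divided so group 2 ends up higher (up) or lower (down) —
and everything is rounded to integers.

What the simulator does not model: library-size heterogeneity, sample
covariates, correlated genes, sequencing error. Passing tests therefore
show correct behavior under independent per-gene families with equal
depths, not robustness to batch structure or normalization failure.

## Evaluation

True FDR is direction-aware (a truth-up gene called down is a false
positive) and defined as FP/max(calls, 1). A configuration fails FDR
control when its mean true FDR exceeds 1.1 Ψ — the 10% tolerance
convention. `sweep_psi` reruns the search over Ψ = 0.01…0.10 on shared
permutation arrays; the false-discovery curve (true FDR vs number of
calls) reads off its table. Replicate aggregation reports means and
paired t comparisons between replicate-matched configurations.

## Problem sizes

The replicated studies in the test suite and the acceptance script use
2000 genes, 6 vs 6 samples, 100 up + 100 down true DEFs, Ψ = 0.05, and
B = B_cal = 50 permutations, with 12 replicates in the suite and 20 in
the acceptance script; the pure-null calibration study uses 600 genes and
20 replicates. These sizes are the package's desk-scale defaults: they
keep a full verification run in minutes while leaving the per-replicate
sampling error of mean true FDR near 0.005, well inside the 10%-of-Ψ
acceptance margin.

## Known limitations

* The realized false count at a boundary fluctuates Poisson-like around
  Ψ·r; FDR control is a statement about means over replicates, not about
  every dataset.
* The linear family cannot express non-monotone interactions between
  attributes; attributes whose information is redundant add grid cost
  without power.
* Permutation FDR needs enough distinct relabelings: N = 4 per group
  (C(8,4) − 1 = 69) is a practical floor for stable estimates, and at
  Ψ = 0.01 small-N estimates are granular.
* `nb_wald` assumes a common dispersion per feature across groups, as do
  the designs it follows.
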