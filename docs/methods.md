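# Methods

## The consolidation model

A compiled QTL is reduced to a pair `(y_i, s_i)`: its peak position on
the consensus map (cM) and a positional standard deviation derived from
its projected 95% confidence interval, `s_i = max(CI_i/3.92, 0.05)` cM.
The factor 3.92 is the two-sided 95% normal quantile span (2 × 1.96); the
0.05 cM floor keeps zero-width published intervals (the catalog contains
a 0.01 cM CI) from producing singular likelihoods.

Per chromosome, the peaks are modelled as a K-component Gaussian mixture
with **fixed, per-observation variances**:

    L(μ, π) = Σ_i log Σ_k π_k N(y_i; μ_k, s_i²)

Free parameters are the K means and K−1 weights, p = 2K − 1. No
component variance is estimated — the confidence intervals are the only
dispersion information a literature compilation carries. This is the
classical meta-QTL model of the Goffinet–Gerber / Veyrieras lineage. The
model assumes projected positions are unbiased for their true locus and
that the published CI is a faithful 95% interval; both assumptions fail
gracefully (a biased or over-confident study pulls its cluster, nothing
else).

### Fitting

Expectation–maximization with the responsibilities in the E-step and
inverse-variance-weighted means in the M-step. Convergence when the
relative log-likelihood change falls below 1e−11, at most 1000
iterations. Starts are deterministic given the seed: component means at
the 1/(K+1)…K/(K+1) position quantiles, four seeded-jitter restarts, and
for small samples an exhaustive multistart — every contiguous partition
of the ordered observations for n ≤ 12, every set partition (run as one
vectorized batch) for n ≤ 8, each with block-proportional initial
weights. For n ≤ 8 the search is therefore globally exhaustive over EM
basins, which the test suite verifies against an independent
enumeration-based oracle. Components are reported in ascending-mean
order; hard assignment is the per-observation posterior argmax.

### Choosing K

K = 1…min(n, 10) by default. Five information criteria are evaluated per
K (p = 2K − 1):

| criterion | formula |
|---|---|
| AIC  | −2lnL + 2p |
| AICc | AIC + 2p(p+1)/(n−p−1) |
| AIC3 | −2lnL + 3p |
| BIC  | −2lnL + p·ln n |
| AWE  | −2lnL + 2p(ln n + 1.5) |

Each criterion votes for its minimizing K; the final K is the modal
vote. Two conventions the source material leaves open are fixed here:
AICc is undefined when n ≤ p + 1, so a criterion that could not evaluate
every K abstains from the vote entirely (avoids comparing partial
minima); vote ties break toward the smaller K (parsimony).

### MQTL summaries

Each hard cluster is pooled by inverse variance: position
`Σ(y_i/s_i²)/Σ(1/s_i²)`, 95% CI width `3.92/√(Σ 1/s_i²)` centred on the
position — strictly narrower than the narrowest member CI except for
singletons. Flanking markers are the nearest consensus markers at or
outside each CI bound (terminal markers clamp at chromosome ends). MQTLs
are named `MQTL_<chromosome>_<index>` by ascending position, 1-based.
Mixtures are fitted per chromosome across all traits jointly, consistent
with multi-trait consensus loci; the trait set of an MQTL is the union
of its members' codes.

## Consensus map and projection

The consensus map preserves the reference map verbatim. A
component-only marker between two shared anchors is placed by linear
interpolation of its offset; placements proposed by several component
maps are averaged when they agree within 5 cM and flagged conflicting
(marker left unplaced) otherwise. A QTL's peak and both CI endpoints are
projected independently, each through its own bracketing shared-anchor
pair (piecewise-linear consistency); anchor hits map exactly. Points
outside the outermost shared anchors are **dropped, not extrapolated** —
extrapolation is unbounded, and dropping is what produces the projection
attrition seen in real compilations. Anchor pairs whose order inverts
between maps flag the group as rearranged; groups with fewer than two
shared anchors are unprojectable.

## Distribution, co-localization and overlap conventions

- Chromosome labels follow the 21-chromosome wheat nomenclature (group
  1–7 × genome A/B/D); counts partition their input exactly.
- Goodness-of-fit against uniformity is Pearson's chi-squared with equal
  expected counts, df = k − 1.
- Density profiles bin signed centromere offsets into half-open
  `[k·50, (k+1)·50)` cM bins; the centromere itself falls in the first
  non-negative bin, short-arm positions get negative offsets.
- The trait incidence matrix is strictly binary (≥1 member QTL of the
  trait). Co-localization of trait A with target B is
  `100·n_both/n_B` **truncated** to an integer — the only convention
  under which the packaged catalog reproduces both published
  frequencies (8/12 → 66 and 10/19 → 52) simultaneously.
- The association test is deliberately the published single-cell
  construction: expected doubly-positive count `n_A·n_B/N`, statistic
  `(n_both − expected)²/expected` on 1 df. This is *not* a full 2×2
  independence test (it ignores the other three cells); the orthodox
  2×2 chi-squared is exposed separately as `chi2_contingency_2x2` for
  diagnosis.
- Physical intervals are closed on Mb reals; a GWAS SNP at an interval
  bound overlaps. Gene-in-interval for synteny uses any-overlap rather
  than full containment so that Mb-rounded published coordinates do not
  drop boundary genes. BED export converts to 0-based half-open bp.
- Ortholog pairs are an input table, not a live database query; rice and
  maize chromosome labels are namespaced `species:chr` so numeric labels
  cannot collide across species.

## Synthetic studies

The generator emulates a literature compilation, not genetics: per
chromosome it plants `n_true_clusters` locus means (stratified placement
with a guaranteed minimum separation), draws member QTLs
`y ~ N(μ, s²)` with `s` from a log-normal CI-width distribution
(median ≈ 13.7 cM by default, matching the compiled study's mean
original CI, so the ~3× CI shrinkage emerges without tuning), assigns
each QTL to one of 27 populations (92–485 lines, RIL/DH mix), and
derives each population's component map from the reference by a
monotone piecewise-linear stretch (factors 0.85–1.18 per anchor
interval) with 50% marker subsampling. Because the distortion's knots
are exactly the retained shared anchors, flanking-anchor projection
inverts it exactly: pipeline recovery error comes from sampling noise
alone. A configured fraction of QTLs is placed beyond the outermost
shared anchor of its component map, so projection attrition is
constructed and exact per seed, not stochastic. Cluster trait sets are
drawn from per-trait base rates with odds multipliers for designated
pairs (Fe/Zn ×6, GY/TKW ×3 by default), giving co-localization a known
truth.

What the generator does **not** emulate: linkage disequilibrium, marker
order errors or translocations (an optional stretch range is the only
map distortion), study-level bias in peak placement, heterogeneous CI
calibration across publications, and trait-dependent detectability.
Passing recovery tests therefore demonstrate correctness of the
consolidation machinery under the stated noise model, not robustness to
mis-calibrated real-world intervals.

Problem sizes used by the validation experiments (chosen as the smallest
sizes at which the checked statistics are stable): the oracle comparison
runs 100 instances of 4–8 observations at K ≤ 4, where exhaustive
partition enumeration is exact; the recovery experiment runs 200
replicates of 3 chromosomes × 3 planted clusters × 6 members with
cluster separation ≥ 5× the largest positional SD (25 cM vs log-normal
widths with median 8 cM), the regime in which a 95% interval is
meaningful for cluster-number recovery.

## Known limitations

- The mixture treats projected positions as independent across studies;
  shared parents between populations violate this mildly.
- For K above the true cluster count the mixture likelihood's supremum
  can be a boundary degeneracy (a component weight tending to zero), so
  "the" K-component optimum is not always attained by an interior
  point; the information-criterion vote makes such K values irrelevant
  in practice.
- The hard posterior-argmax clustering maximizes the mixture
  likelihood, not the classification likelihood; the two coincide for
  separated clusters but can differ for heavily overlapping
  compilations.
- Physical anchoring inherits whatever error the marker position table
  carries; no sequence-level verification is attempted.
- The published catalog fixture records trait sets but not member QTL
  identities (those were never published), so member-level statistics
  are only available for synthetic or user-supplied compilations.
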