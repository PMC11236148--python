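# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the design decisions that were genuinely open.

## Data model

An abundance table is a samples × species matrix of non-negative
individual counts from direct enumeration of cultured morphospecies.
Blank cells on read are **true zeros** — in a culture count an absence is
an observation, not missingness. Environmental tables may contain missing
values; they propagate as pairwise exclusion (a sample without a value for
a factor drops out of that factor's distance matrix only). Taxonomy is a
strict four-rank lineage (genus, family, order, class) with enforced
consistency: one family cannot sit in two orders. Percentages in
composition summaries are rounded half-up to two decimals, matching how
such survey tables are conventionally printed; note that a summary with
many taxa accumulates up to 0.005 × n_taxa of rounding error in its
column sum.

## Synthetic surveys

The generator emulates a plateau river-basin design: 20 sites allocated
round-robin over four habitats (grassland, farmland, wetland,
sea-buckthorn forest), each sampled in three seasons → 60 samples;
200 morphospecies; 1000 individuals enumerated per sample.

* **Metacommunity.** Relative abundances are drawn from a Fisher
  log-series whose α solves `S = α ln(1 + N_tot/α)` at the scenario's
  total count, giving the strongly skewed rank-abundance structure real
  ciliate surveys show. A log-normal option (σ = 1.5) exists.
* **Neutral draw.** Each local community is a Dirichlet-multinomial
  sample: λ ~ Dirichlet(N·m·p), counts ~ Multinomial(N, λ). This is the
  stationary Sloan/Hubbell approximation — species frequencies across
  communities are Beta(Nm·p, Nm·(1−p)) distributed — chosen over explicit
  birth–death simulation because it matches the distributional assumption
  of the downstream fit and is orders of magnitude faster. Per-sample
  totals equal N exactly.
* **Filtering.** Species carry uniform niche optima on a 0–100 % SWC axis;
  site weights are `p · exp(−s·((SWC−opt)/100)²)`, renormalised, with
  strength `s ≥ 0`. SWC is a site property drawn from non-overlapping
  per-habitat ranges (wetland wettest); all other factors are drawn
  independently of the community, so only SWC carries real signal.
  At `s = 0` the kernel is flat and the filtered path is draw-for-draw
  identical to the neutral one (the community random stream is separate
  from the environment and niche streams).
* **Randomness.** All draws flow from one scenario seed through named
  `numpy.random` child streams; nothing touches global state.

What it does **not** emulate: spatial dispersal kernels, temporal
autocorrelation between seasons (seasons are independent redraws),
compositional artefacts of relative-abundance pipelines, taxonomic
misidentification, or encystment dynamics. Passing tests on synthetic
data therefore demonstrate correctness of the statistical machinery under
the stated model, not field realism; seasonal turnover magnitude is
deliberately a free parameter, not a calibrated one.

## Diversity and C/P

Natural logarithms throughout; Shannon H is in nats. Group-level H and D
default to **means of per-sample values** (the "average diversity index"
convention); a pooled mode recomputes indices on summed counts.
Margalef D at S = 1 is defined as 0. The C/P quotient defaults to species
**richness** (presence), not abundance, because the quotient is defined on
species counts; an abundance basis is provided since the bioindication
literature varies. A zero denominator (no polyhymenophoran species in
scope) is flagged as undefined rather than reported as infinity.
Group comparisons default to permutation tests (999 shuffles, seeded),
which are better calibrated than ANOVA at the group sizes typical of
seasonal soil surveys; one-way ANOVA with Tukey HSD is available.

## β diversity

Bray–Curtis is computed on raw counts by default (`relativize=True`
converts to per-sample proportions first); with equal per-sample totals
the two coincide up to scale. NMDS is non-metric MDS minimising Kruskal
stress-1: k = 2, 50 random restarts, 500 iterations, best configuration
kept, deterministic under seed. PERMANOVA uses the pseudo-F on squared
distances with whole-label permutations and
`p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`, so the attainable minimum is
`1/(n_perm+1)`.

## Networks and keystones

Edges join species whose abundance profiles across the in-scope samples
correlate with |r| ≥ 0.6 at BH-adjusted p ≤ 0.05 (Spearman by default);
species present in fewer than 3 samples are removed before correlation
and constant vectors are dropped with a warning. These thresholds follow
common microbial co-occurrence practice and are configuration-exposed;
published node/edge counts from any particular survey depend on the
original (usually unstated) thresholds, so only the panel's internal
arithmetic (average degree = 2E/N, density = 2E/(N(N−1))) is expected to
reproduce exactly.

Topology metrics are unweighted (edge presence), except modularity, which
ignores sign and uses |r| as weight. Mean path length averages over
connected pairs only, keeping fragmented graphs finite. Module detection
defaults to deterministic greedy (Clauset–Newman–Moore) agglomeration;
Louvain with a seed is optional. Modules are numbered 1..k by descending
size with lexicographic tie-break, making partitions reproducible.

Zi uses the **within-module** degree standardised over the module's
members (population SD; a zero-spread module gives its members Zi = 0);
Pi uses the node's **total** degree in the denominator (Guimerà–Amaral
convention — the two Kᵢ symbols in the defining equations refer to
different quantities). Role thresholds are strict: Zi > 2.5 and/or
Pi > 0.62 lift a node out of the peripheral class; boundary-equal values
stay in the lower category. An isolated node's Pi is set to 0 with a
warning. Connectors, module hubs and network hubs together form the
keystone candidate list, sorted by role then Zi + Pi.

## Environmental drivers

Environmental distance is the absolute pairwise difference of one factor
at a time — one Mantel test per factor — with a combined z-scored
Euclidean option. Mantel r correlates the off-diagonal entries (Pearson
or Spearman via rank-transforming both matrices once; permuting samples
permutes a fixed multiset of entries, so ranks stay consistent); p is
one-sided from joint row/column permutation. Geographic distance is
great-circle (haversine, R = 6371 km). Distance-decay regressions are
OLS of community dissimilarity on a pairwise predictor difference, but
their significance comes from Mantel-style permutation, **not** the
t-distribution: pairwise dissimilarities sharing a sample are not
independent, and parametric p-values on n(n−1)/2 "observations" would be
anti-conservative. A constant predictor yields a flagged, undefined fit.

## Neutral model

For each species: observed frequency = fraction of in-scope samples where
present; p̄ = mean relative abundance across samples. Predicted frequency
is `1 − BetaCDF(d; Nm·p̄, Nm·(1−p̄))` with N = mean per-sample total.
m is estimated by bounded scalar least squares on m ∈ (10⁻⁶, 1]
(tolerance 10⁻⁸; the SSE is smooth and unimodal in m, and the optimizer
is verified against a brute-force grid in the tests). R² = 1 − SSres/SStot
is reported as computed — it can be negative and is never clamped; if all
species are present everywhere SStot = 0 and R² is flagged undefined.

**Detection limit.** The curve's d is the relative abundance at which a
species counts as "detectable". For enumerated counts the probability of
detecting a species at abundance λ in a sample of N individuals is
1 − (1−λ)^N ≈ 1 − e^(−Nλ), which crosses ½ at λ = ln 2/N. We therefore
default to **d = ln 2/N**: matching the threshold model to the median of
the actual detection process makes the least-squares m estimator
consistent for count data (fitting the exact beta-binomial occurrence
curve with the common d = 1/N instead biases m̂ upward by ≈ 25 % at
Nm = 100, N = 1000). `detection_limit` is configurable, with `1/N`
available for comparison with other implementations.

The 95 % envelope is the Wilson score interval of the predicted frequency
at the realised number of samples — the beta-model occurrence probability
combined with binomial sampling error — and species are partitioned as
below/within/above it.

## Problem sizes and calibration

The validation experiments run at sizes chosen to make the statistics
sharp while keeping the whole suite quick on a laptop: neutral-model
recovery uses 20 replicate surveys of 60 samples × 150 species at
m = 0.1, N = 1000; permutation-test calibration uses 1000 null data sets
of 14 samples with 99 permutations each (at α = 0.05 the p-value
granularity of 99 permutations makes the rejection rule unbiased);
the Zi–Pi implementation is checked against brute-force adjacency
enumeration on 100 random graphs of ≤ 12 nodes to 10⁻¹².

## Known limitations

- Correlation networks on raw counts carry compositional bias; no
  SparCC/SPIEC-EASI-style correction is attempted.
- The NCM fit treats species as independent observations on the
  occurrence-frequency curve; envelope coverage is pointwise, not joint.
- Greedy modularity is a heuristic; partitions (and hence Zi/Pi) can
  differ from Louvain's on ambiguous graphs.
- Group-level diversity means inherit the per-sample estimator's bias at
  very small N; no coverage-based standardisation is provided.
- NMDS stress comparisons across k use the best of equal restart budgets;
  with few restarts a higher-k run can occasionally land in a worse local
  optimum.
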