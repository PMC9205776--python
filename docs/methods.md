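# Methods

## Contact-matrix model and processing

A `ContactMatrix` holds one chromosome's cis contacts on a fixed bin grid
(0-based, half-open bins; position → bin `floor(pos/resolution)`), stored as
the upper triangle (`bin_i ≤ bin_j`).  The `total` counts off-diagonal
pixels twice, i.e. it is the sum of the full symmetric matrix, matching how
sequencing depth is quoted.  A processing `stage` moves forward only:
`raw → balanced → scaled → oe`.

**ICE balancing.**  Plain iterative correction: repeatedly divide by the
unit-mean marginal vector (diagonal included once in marginals) until the
coefficient of variation of non-masked marginals falls below `tol`
(default 1e-5; `max_iter` 1000 — plain ICE converges linearly and sparse
matrices can need several hundred sweeps).  Bins with zero coverage, plus
the lowest-coverage `mask_frac` (default 2%) of bins, are masked: bias 0,
rows emptied.  Returned biases satisfy `out_ij = raw_ij · b_i · b_j` with
unit mean over active bins, so balancing is exactly reproducible from the
bias vector.  Re-balancing a balanced matrix is a fixed point (tested).

**Scaling and subsampling.**  `scale_to_total` rescales linearly (default
target 1e8 contacts).  Balancing is applied before scaling; the order is
immaterial for every O/E-based analysis downstream.  `subsample_contacts`
thins each pixel binomially with probability `target/total` — equal in
expectation to read-level subsampling and cheap at any depth; an `exact`
flag draws a multinomial over pixels when the realized total must match
exactly.

**Expected profile and O/E.**  `expected_by_distance` averages over *all*
in-range, non-masked bin pairs at each separation, zeros included — the true
mean over possible pairs, so O/E of a matrix against its own expected has
per-diagonal mean exactly 1.  Pairs touching masked bins are excluded from
numerator and denominator alike.  `oe_transform` drops pixels whose
expected value is zero.

## Aggregation

**APA.**  For each loop, the submatrix rows = 5′ anchor ± flank, columns =
3′ anchor ± flank (flank default 100 kb, side `2·flank/res + 1`) is
averaged over loops; loops whose window crosses a chromosome edge are
skipped, not padded — padding would bias the mean.  The APA score is the
mean of the central `size × size` block (default 3).  Primary and extended
loop APA runs on ICE-balanced, depth-scaled matrices; stripe analysis on
expected-normalized signal.  Both functions accept other stages with a
logged note rather than an error, since O/E input is a legitimate variant.

**Extended loops.**  Every primary loop's 5′ anchor is paired with every
distinct 3′ anchor from the full loop list within a 3-Mb window measured
from the 5′ anchor, boundary inclusive; pairs present anywhere in the
primary list are excluded; output is deduplicated.  A flag restricts
candidates to pairs longer than their seed primary loop (default off).
The enumerator is verified against an exhaustive O(n²) reference on 1,000
random loop lists.

**Aggregate stripes.**  Around each anchor's diagonal pixel a
`(2·flank/res+1)`-sided window (flank default 3 Mb, i.e. a 6-Mb submatrix)
is divided element-wise by the matrix's expected value at each pixel's
separation, then averaged.  Within a diagonal-centered window the
separation of pixel (r, q) is |r−q|, so the divisor is one Toeplitz matrix
shared by all sites.  The 3′ profile is the center row rightward from the
anchor, the 5′ profile the center column upward (reversed so distance
increases); anchors are used unoriented and both profiles are reported,
since aggregate stripe analysis does not require motif orientation.

**LOESS.**  Local polynomial regression with tricube weights over the
`span`-nearest neighbors (span 0.75, local degree 2 by default; the stripe
quantification uses two independent 1-D fits, one per arm — a joint 2-D
surface adds nothing for profiles indexed by a single distance).  The fit
at x₀ is the linear functional l(x₀)ᵀy of a weighted least-squares local
polynomial; the residual variance is estimated from the smoother matrix at
the data points, σ̂² = RSS / (n − 2·tr L + tr LᵀL), and the 95% band is
fitted ± 1.96·σ̂·‖l(x₀)‖.  Fitted values agree with R's `stats::loess`
(`surface="direct"`) to ~1e-6 on smooth data (cross-checked in the test
suite); pointwise coverage of a noisy straight line is ~95% (Monte-Carlo,
200 runs).

**Stripe decay-length estimation.**  The quantity of interest in the
genotype comparison is how fast the stripe decays with distance.  Fitting
an exponential to the raw aggregate profile is badly biased by three
nuisance effects: the focal loop "dots" that sit on the stripe at other
anchors, the contribution of the features themselves to the expected
profile, and the multiplicative row-scaling that balancing applies to
anchor bins.  `stripe_decay_profiles` therefore (i) masks pixels within
±3 bins of any other anchor (dots and crossing stripes live at
anchor/anchor pixels), and (ii) normalizes each distance by a control
profile over bin pairs that both lie away from every anchor, which cancels
the distance structure of the denominator exactly.  `recover_stripe_decay`
pools the 5′/3′ profiles of several replicate maps (default 8; merging
replicate libraries before aggregate analysis is standard practice), uses
the replicate scatter as per-distance standard errors, and fits
`c + A·exp(−d/L)` by robust (soft-L1) least squares over 0.5–5 Mb with a
multi-start over initial L.  The fit starts at 500 kb because the first few
bins are dominated by short-range contact mass that dilutes the relative
stripe signal, and the baseline is bounded in [0.85, 1.15] — the control
normalization pins it near 1 by construction.  On the generator's defaults
this recovers planted L ∈ [0.25, 2] Mb with errors of a few percent
(worst observed ~15% across independent batches).

## Screen statistics

Counting insertions per gene is upstream; the unit of analysis is the
per-gene (sense, antisense) pair.  Step 1 is an exact two-sided binomial
test (the "minlike" convention: total probability of outcomes no more
likely than the observed one) of the sense count against a null sense
fraction — by default the dataset-wide sense fraction ("auto"), since the
genome-wide insertion pool defines the expected orientation balance; 0.5 is
available.  Benjamini–Hochberg correction runs over genes with at least one
insertion; significance is q < 0.05 with a sense/antisense direction label.
The two-sided p is computed vectorized (grouped by total, cumulative sums
over pmf-sorted outcomes) and is identical to `scipy.stats.binomtest`
(asserted in tests); this keeps 20,000-gene × many-seed calibration runs at
sub-second cost.

Step 2 is a two-sided ("bidirectional") Fisher exact test of the case
counts against **each** control separately; a gene passes only if p < 0.05
versus every control.  The aggregated-control filter sums control counts
element-wise, requires the cross-product odds ratio ≥ 0.7 (values > 1 mean
relative sense enrichment in the case; 0.5 added to every cell only when a
cell is zero, and only for the OR, never for p) and a one-sided
(sense-greater) Fisher p < 0.05.  A table with a zero margin has p = 1 by
convention.  A *fitness enhancer* must be step-1 sense-enriched in the case
and in no control, pass step 2 versus all controls, and pass the OR filter;
hits are ranked by the aggregated one-sided p.  Because the flag is a
conjunction, the classifier evaluates step-2/OR statistics only for step-1
survivors by default (`full=True` computes every gene) — the flag set is
unchanged and null-calibration runs stay fast.  Fisher p-values are
verified against full hypergeometric enumeration for all tables with total
≤ 30.

## Synthetic data

The contact-map generator is phenomenological.  Pixel intensity:

```
λ_ij = B·(|i−j|+1)^(−α) · (1 + loops + extended loops + stripes)
     + S·exp(−|i−j|·res / ℓ_short)
```

with Gaussian loop bumps (amplitude 4, width 1 bin) at consecutive
anchor pairs, extended-loop bumps (amplitude 0.4–3.0 by genotype) at the
enumerated extended pairs, and stripes `A_S·exp(−d/L)` (A_S = 2) along each
anchor's row and column.  Counts are Poisson after scaling λ to the target
depth (default 10⁷ for a 50-Mb chromosome at 100-kb bins — a deeply
sequenced map; at this depth single-profile noise is ~3–5% per point).

The additive short-range term (S = 35, ℓ_short = 50 kb) models the
sub-200-kb contact mass that dominates real cis coverage, and the planted
features deliberately do **not** multiply it.  This matters: a bin's ICE
bias is set by its total coverage, and if stripes carried a large share of
an anchor bin's marginal, balancing would suppress anchor rows by a factor
that grows with L — flattening and even inverting the planted ordering.
With short-range mass dominating the marginal (as in real maps), anchor
bins stay within a few percent of their neighbors and the planted signal
survives balancing.  Stripes are exponential with a single decay length L
as the "extrusion reach" knob; TAD-scale block enrichment is omitted
(available via explicit parameters) since no analysis here depends on it.

Genotype presets share one anchor/loop layout (jittered ~1.2-Mb spacing
inside a 3.3-Mb margin, log-normal site scores) so maps differ only in the
planted parameters and count noise.  Preset L values
(0.3 / 0.6 / 1.0 / 1.4 / 2.0 Mb for dHDAC8 / WT / dESCO1 / dWAPL /
dESCO1_dWAPL; 1.2 and 1.1 Mb for the PDS5A knockouts, which also drop the
focal loop amplitude to 1.5) are configuration encoding the qualitative
phenotype ordering, not measurements.

The screen generator draws per-gene expected totals log-normal across genes
(median 100 insertions, log-sd 1 — about 2 million insertions over 20,000
genes, typical of deep HAP1 gene-trap screens), shared between samples;
realized totals are Poisson, sense counts Binomial(total, p_g) with
p_g = 0.5 under the null.  Planted fitness enhancers get an elevated sense
fraction and a clonal-expansion factor in the case only; a planted gene's
base expected total is pinned to the median so the planted effect size is
reproducible across seeds.

## What the synthetic benchmarks do and do not show

Passing tests demonstrate that the implementation is internally correct
(oracle agreement), well calibrated (null screens flag < 1 gene per run;
LOESS bands cover at ~95%), and powerful enough to recover planted effects
of realistic size (genotype ordering 10/10 seeds; L within 20%; a strong
planted enhancer flagged and ranked first in ≥ 19/20 seeds).  They do not
show that real Hi-C maps follow a separable power-law × enrichment model,
that real stripes are exponential, or that insertion counts are
Poisson-binomial — real data add TADs/compartments, mappability structure,
replicate batch effects, and overdispersion that the generator deliberately
omits.  The generator is a correctness and sensitivity harness, not a data
model.

## Numerical choices and degenerate inputs

* Bin mapping is `floor(pos/resolution)`; anchors and loop midpoints map
  through the same rule, so pileups are reproducible to the pixel.
* Ties in top-site selection break by (chrom, position) ascending —
  deterministic output under equal scores.
* `percent_sense` of a gene with no insertions is NaN and excluded from
  fishtail coordinates and BH correction.
* Every stochastic operation takes an explicit integer seed; pipelines
  split one root seed per stage with `numpy.random.default_rng`.
* Problem sizes in the tests and the acceptance script (50-Mb single
  chromosome, 36 anchors, 20,000-gene screens, 8 replicate maps for decay
  fits, 200-run Monte-Carlo for coverage) are chosen so each statistical
  margin is several standard errors wide while the whole suite runs in a
  couple of minutes.

## Known limitations

* One chromosome per matrix; trans contacts, multi-resolution stores and
  `.hic`/cooler export are out of scope (triplet text + chrom-sizes is the
  interchange format).
* The stripe model has no CTCF motif orientation; both arms are emitted and
  averaged.  Real stripe asymmetry would require oriented anchors.
* The decay-length estimator assumes a single-exponential stripe on a
  feature-free control background; on real data with nested loop arrays the
  dot-masking radius (±3 bins) and the fit window would need re-tuning.
* Step-2's "significant against every control" rule makes power depend on
  the weakest control's depth; with shallow controls a jointly-stratified
  test would be more powerful, but the severally-applied rule is the one
  implemented.
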