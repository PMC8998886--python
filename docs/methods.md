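# Methods

This note documents the statistical model behind `metabnet`, the parameters
that matter, the synthetic generator and what passing tests do and do not
show, and the numerical/design choices made where the design was open.

## Network inference

### Correlation gate

For each metabolite–transcript and metabolite–metabolite pair, Pearson r is
computed over pairwise-complete observations (missing cells are dropped per
pair, never imputed — metabolite panels routinely contain gaps and any
imputation scheme would be an invention). The two-sided p-value uses the
exact transform t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom, with
p = 0 at |r| = 1. A pair with fewer than `min_pairs` complete observations
(default 10) or a constant member yields a "not computable" marker and is
skipped, never an exception mid-scan.

Candidates are pairs with raw p ≤ `p_threshold` (default 0.001). The gate is
deliberately applied to raw p-values: multiple-testing correction is a
reporting device for the evaluation layer, not part of the edge definition,
and the same gate applies to both pair kinds. With N null pairs the gate
passes ≈ 0.001·N spurious candidates; this floor, not the estimator, sets
the precision obtainable on data with few true associations.

### DPI pruning

For every triplet (m₁, m₂, t) whose three correlations are all in the
candidate set, the edge with strictly the lowest |r| is flagged as indirect
if it is a metabolite–transcript edge. Numerical choices:

* **Strict inequality, no tolerance.** Exact ties keep all edges. A
  tolerance knob exists in some co-occurrence tools but has no principled
  default here; omitting it keeps the operation exactly reproducible.
* **One pass, no cascading.** Flags are computed against the pre-DPI edge
  set, so removal order cannot influence the result; the output is
  independent of triplet enumeration order by construction.
* Metabolite–metabolite correlations participate in triplets but are never
  emitted as edges; the network is strictly bipartite-hubbed.

### Bootstrap likelihood

Samples are resampled with replacement at full size B times (default 100),
all B draws from one seeded generator. In each resample, candidate pairs are
re-correlated; an edge is *supported* iff its per-bootstrap p passes the gate
AND it survives DPI recomputed within that bootstrap (support is meant to
measure whether the edge would have been called at all on that resample, and
an edge that loses its triplet is not called). A pair that becomes constant
in a resample counts as unsupported there. The per-bootstrap p (rather than
the full-data p) is used because each bootstrap is treated as a fresh
inference; this is documented as this package's contract.

The final network keeps candidates that survive the full-data DPI **or**
have support k ≥ 1 (the "at least one bootstrap" recovery rule), with
likelihood ℓ = k/B. A full-data survivor with k = 0 gets the floor ℓ = 1/B
so that every stored edge retains positive weight in enrichment scoring —
a zero-weight edge would silently vanish from predictions.

## Prediction

### Signatures

* Sample mode: per-gene z-score across samples (mean and n−1 sd of the
  dataset itself). No external reference profile is supported; "relative to
  the dataset mean" is the contract.
* Contrast mode: per-gene Welch t-statistic (group1 − group2). Welch is used
  because the contrast scenarios of interest have small and unequal groups
  with no variance-homogeneity guarantee. Genes constant in both groups
  score 0 with a warning.

### NES

All G signature genes are rank-transformed to normal quantiles
q_g = Φ⁻¹(rank_g/(G+1)) (average ranks on ties). The rank pool is the whole
signature, not just network genes, so targets are ranked against the
transcriptome background. With weights w_g = r_g·ℓ_g,

    NES = Σ_{g∈targets} w_g·q_g / √(Σ w_g²),

two-sided p = 2·Φ(−|NES|). Properties that follow directly and are enforced
by tests: invariance under uniform positive weight rescaling, equivariance
under signature negation, invariance under target order, NES exactly 0 for a
sample sitting at the dataset mean, and a standard-normal null (mean ≈ 0,
sd ≈ 1; the sd sits slightly below 1 because the quantile grid's variance is
G/(G+1)-ish, well inside any practical tolerance for G in the hundreds).

**What the null is.** The N(0,1) calibration holds when target scores are
exchangeable with the background — e.g. expression with no
metabolite–transcript structure. It does *not* hold for a shift-0 two-group
contrast on data that contains the planted modules: the targets of one
metabolite co-vary through their shared latent factor, their Welch t's are
mutually correlated, and the NES variance is inflated. That inflation is a
property of the data, not a miscalibration of the score; the uniformity
check is therefore defined on structure-free expression.

`minsize` (default 10) counts a metabolite's network targets *measured in
the prediction dataset*; metabolites below it are skipped with a recorded
reason rather than scored noisily. Gene ids are matched exactly after
case/whitespace/underscore normalization — never fuzzily, since approximate
matching of metabolite or gene names fabricates overlap.

## Evaluation

* Per-metabolite predicted-vs-measured Pearson r across shared samples,
  BH-FDR across metabolites, and a three-way classification
  (positive-significant / negative-significant / non-significant) at
  α = 0.05. Significance is reported both on BH-adjusted and on nominal
  p-values (`class_adj`, `class_nominal`): conventions differ between
  blanket-FDR reporting and per-figure nominal thresholds, so both are
  exposed and `class_adj` is the default.
* Split-half validation: repeated random partition into floor(n/2) training
  and the remainder testing; the network is re-inferred per split (inner
  B is a parameter — 10 in the test suite, where it changes nothing
  qualitatively and keeps 50 splits around ten seconds at n = 300) and
  sample-mode predictions on the test half are scored per metabolite.
* Shuffled-network null: each edge's transcript endpoint is redrawn with
  replacement from the multiset of transcript endpoints, so relabeling
  probability is proportional to degree; per-metabolite degree, r, ℓ and
  DPI flags are preserved. Duplicate (metabolite, transcript) collisions are
  redrawn up to 100 times, then dropped with a warning — the redraw bound is
  this package's choice; only the degree-proportional law is contractual.
* One-tail Wilcoxon signed-rank (shift above 0): exact distribution of the
  positive-rank sum via its generating polynomial for n ≤ 25 without ties in
  |values|; normal approximation with tie correction and 0.5 continuity
  correction otherwise. Zeros are discarded. Under strict exact enumeration
  a two-point symmetric input like (−x, +x) yields p = 3/4 (W⁺ ∈ {0, 1.5,
  1.5, 3}), which is the convention implemented; mid-p variants would lower
  it but break the exact all-positive case P(W⁺ ≥ n(n+1)/2) = 2⁻ⁿ.
* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
  an independent step-up oracle guards it in the tests.

## Synthetic generator

Linear-Gaussian by design — the pipeline is Pearson-based, so the generator
lives exactly on the estimator's assumptions:

* latent activities a ~ MVN(0, C); C defaults to identity, a scalar coupling
  c couples consecutive metabolite pairs at c (the minimal structure that
  exercises DPI triplets), or a full PSD matrix may be given;
* measured metabolite x_m = a_m + N(0, σ_m²), σ_m default 0.5;
* target transcript t_g = s_g·β_g·a_m + N(0, 1) — target noise sd is fixed
  at 1 so β alone tunes strength and the closed form stays simple:
  ρ = s·β/√((1+σ_m²)(β²+1));
* background transcripts iid N(0, 1).

Defaults (20 metabolites × 20 disjoint targets, β ∈ [0.8, 1.5] ⇒ |ρ| ≈
0.56–0.74, 30% negative signs, 400 background transcripts, n = 300 training /
n = 57 held-out) mirror the scale of public paired cancer cell-line panels,
where the strongest metabolite–transcript correlations sit in the 0.3–0.8
band and the smaller panel has ~57 usable samples. The contrast scenario
shifts the latent activity of an affected subset in group 2, leaving the
observation model untouched.

**What passing tests show — and don't.** The generator has Gaussian margins,
linear effects, homoskedastic noise, disjoint modules, and at most
missing-at-random gaps. Real panels have heavy tails, batch structure,
platform-censored metabolite values, shared pathway genes, and name-matching
losses. Green tests certify the machinery (gate, DPI, bootstrap, NES,
nulls) under the model's assumptions; they do not certify effect sizes on
real data.

## Degenerate inputs and tie-breaks

Duplicate feature ids, non-numeric cells, empty sample intersections, empty
gene intersections, out-of-range network fields, and all-constant matrices
are hard errors naming the offender. Constant rows are dropped (z-scoring,
signatures) or skipped (correlation) with logs. DPI ties keep all edges;
rank ties use average ranks. Bootstrap resampling indexes samples by
position, so likelihoods are reproducible for a fixed seed and column order;
full-data r, p and DPI flags are invariant to sample order exactly.

## Known limitations

* DPI only handles metabolite–metabolite–transcript triplets; higher-order
  indirect structures pass through (a partial-correlation extension is out
  of scope). Under strong coupling the bootstrap recovery rule readmits a
  share of indirect edges (they win DPI in some resamples), which is the
  method's documented behavior — precision under coupling is bounded by it.
* Transcript–transcript edges, mutual-information scores, imputation,
  raw-count normalization and survival modeling are out of scope; inputs
  are expected pre-normalized (log-scale expression, scaled metabolite
  units).
* The NES p-value is analytic, not permutation-based; for contrasts on data
  with strong co-regulation it is anti-conservative (see "What the null
  is").
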