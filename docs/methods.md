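# Methods

This note documents the models, formulas, numerical choices and known
limitations behind `mirser`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## Data model

A Ct value is the PCR cycle at which a well's fluorescence crosses
threshold; one cycle earlier means roughly twice the starting template. A
well that never crosses threshold within the run's cycle limit is
*undetected* — missing data, not "Ct = 0" and not "quantity = 0". Internally
the sentinel is `nan` so arithmetic propagates it; on disk it is the
configurable token `Undetermined` (the TaqMan export convention) or an
empty cell. Ct values are stored at full float precision and written with 4
decimals, which round-trips typical instrument exports losslessly. The
reader auto-detects tab or comma delimiters, since both dialects occur in
practice. The panel model assumes one well per assay per card; replicate
wells per assay are not modelled.

## Detection filter

An assay enters the serum analysis only if it has a non-sentinel Ct below
`max_ct` (default 40, the card's cycle limit — i.e. any amplified well
counts as detected) in **every** sample. This is the "detected in all
samples" rule; it avoids imputing undetected wells at the cost of dropping
assays near the limit of detection. The filter is idempotent and never
touches the sample set.

## Normalization schemes

Serum lacks a stable endogenous control, so two independent schemes are
used and later reconciled:

**Variance-stabilized amounts (`VSN_AMOUNT`).** Each Ct becomes a linear
amount `a = 2^(50 − Ct)`, anchoring one arbitrary unit at Ct 50. Each
sample j is scaled by its median amount `s_j` and transformed by
`h(a) = arcsinh(c · a / s_j)`. The arcsinh is the standard generalized-log
shape: linear near zero, logarithmic for large values, so
multiplicative (high-abundance) and additive (low-abundance) noise are
put on a comparable footing. Numerical choices:

- `c = 2^20` is a *fixed* constant (the amount of a mid-panel well at
  Ct 30). A data-dependent `c` would make the output depend on the sample
  set's overall level; a fixed `c` makes the transform an exact function of
  the within-sample amount ratios `a/s_j`, and therefore exactly invariant
  to per-sample additive Ct offsets.
- After the transform, residual per-sample median differences are removed
  by an additive shift on the stabilized scale (a multiplicative rescale of
  amounts). This step exists because the interpolated median of an
  even-sized sample does not commute with arcsinh; without it the
  per-sample medians agree only to ~1%, with it they agree exactly.
- The transform requires strictly positive output; after the detection
  filter the smallest stabilized values sit far from zero, and the code
  raises rather than emitting non-positive values if fed data outside the
  transform's working range.

This scheme reproduces the *intent* of model-based variance-stabilizing
normalization (affine per-sample calibration followed by a glog transform)
with a fully specified, dependency-free procedure; it does not fit
calibration parameters by maximum likelihood.

**Invariant delta-Ct (`INVARIANT`).** Per sample, the reference
`r_j` is the arithmetic mean Ct of four empirically stable serum miRNAs
(mmu-miR-146a-5p, mmu-miR-16-5p, mmu-miR-30e-5p, mmu-miR-744-5p;
overridable), and each assay's quantity is `2^(r_j − Ct)`. The arithmetic
mean of Ct values equals the geometric mean of quantities — standard
delta-Ct practice. A global Ct shift on a sample moves `r_j` and every Ct
equally and cancels exactly. Every invariant assay must be present and
detected in every sample; the error names the offending assay and sample.

Both schemes are monotone in −Ct within a sample, so within-sample
abundance ranks are preserved; both cancel per-sample offsets (exactly, in
both cases, by construction).

## Differential testing and consensus

Each target assay (spike-ins, references and U6 are excluded from target
statistics) is tested between case and control groups with Welch's
unequal-variance two-tailed t test on **log2 quantities**, using
Welch–Satterthwaite degrees of freedom; significance is `p < 0.05` with no
multiple-testing correction — the workflow controls false positives through
the dual-method consensus rather than through multiplicity adjustment, and
α is exposed as configuration. Log2 is applied uniformly to both methods'
quantity matrices for symmetric treatment of increases and decreases; for
the stabilized scale this is a second monotone compression that leaves
calls' directions and ranks unchanged. The t test itself is delegated to
`scipy.stats.ttest_ind(equal_var=False)`; the suite cross-checks it against
an independently coded evaluation of the Welch formulas at 1e-10.

Degenerate inputs: groups with fewer than 2 values raise; two constant
groups with equal values return `(t=0, p=1)` by convention; two constant
groups with different values raise, since t is undefined. Constancy is
detected by zero *range*, not by the computed variance — floating-point
summation of identical values can produce an ulp-scale nonzero variance
and, with it, an O(1) spurious t statistic.

A miRNA is a **consensus** call when significant under both schemes; its
direction (increased/decreased in cases) is the shared sign of the log2
fold change. Dual-significant assays with discordant signs are excluded
from the partition and reported separately — a conservative choice for a
case the underlying workflow does not address. Agreement between the two
schemes' binary calls over the tested universe is Cohen's kappa,
`(p_o − p_e)/(1 − p_e)`, with chance agreement from the marginal products;
the degenerate all-agree table returns 1.0 exactly. Kappa is reported at 2
decimals, matching customary reporting. `agreement_table_from_margins`
reconstructs the 2×2 table from the counts a profiling report prints
(tested / per-method significant / shared), which is how the worked-example
kappas of 0.71 and 0.57 are recomputed.

## Tissue origin attribution

Tissue (unlike serum) has a usable endogenous control, U6 snRNA:
`q = 2^(Ct(U6,j) − Ct(x,j))` per sample. Assays are ranked by mean
quantity over replicate lysates; assays detected in at least one replicate
are averaged over their detected replicates and retained (configurable to
intersection-only via upstream filtering), assays detected nowhere are
excluded. Rank ties break lexicographically by assay name so output is
deterministic. "Average normalized quantity" is averaged on the linear
quantity scale, not the ΔCt scale; the two differ only at near-ties.
`top_n_membership` counts how many of a serum-changed set sit at tissue
rank ≤ n; members absent from the tissue ranking count as misses and are
listed. A hypergeometric comparison of the observed count against the
chance expectation `k·n/M` is available as a diagnostic in the test suite;
it is not part of the core pipeline output.

## Spike-in qPCR quantification

Two synthetic C. elegans miRNAs (cel-miR-39-3p at low input, cel-miR-54-3p
at 1,000-fold higher input) are spiked before RNA extraction. Relative
expression is `2^(mean(Ct_39, Ct_54) − Ct(x))` — the two spike-in Cts are
averaged *despite* the input difference; the average is offset from either
alone by the constant log2(ratio)/2, which cancels in every group contrast,
so relative expressions are arbitrary-unit by design. The known ratio gives
an internal accuracy check: the per-sample ΔCt (low-input minus high-input)
should equal log2(1000) = 9.9658 cycles under equal amplification
efficiency, and — being pure chemistry — should not differ between
biological groups (Welch test). Group fold change is the ratio of
arithmetic group means on the linear scale, matching how relative
quantities are usually presented; a geometric-mean variant is available,
and the p-value always comes from the Welch test on log2 values. No
amplification-efficiency modelling or standard-curve fitting is attempted.

## Synthetic data generator

The generator exists so every stage is testable with known ground truth.
Model per well: `Ct(x,j) = baseline(x) + effect(x)·1[j is case] +
offset(j) + ε(x,j)`, with `ε ~ N(0, σ²)` (additive Gaussian on the Ct
scale = log-normal on the quantity scale, the standard qPCR error model)
and `offset(j) ~ N(0, 1.0²)` a per-sample global shift emulating
extraction/input variation. Dropout is deterministic censoring at the
limit of detection (Ct > 40 → undetected) — simpler than stochastic
amplification failure and sufficient for exercising the detection filter.
Defaults, chosen to mirror the study designs:

- **Serum**: 768 assays (762 targets + 4 invariant references + 2
  spike-ins); groups 3 wild-type/0 weeks, 3 mutant/2 weeks, 3 mutant/4
  weeks; expressed targets draw baselines uniformly from [22, 36] Ct;
  σ = 0.5 per well. Half the targets (`fraction_expressed = 0.5`) are
  "absent from serum" with baselines above the detection limit
  ([41, 46]) — the baseline range alone cannot reproduce the observed
  roughly-half detected-in-all fraction, because any baseline below 36 is
  detected essentially always; panel composition has to carry that
  structure. With these defaults 387/768 = 50.4% of assays are detected in
  all 9 samples. 30 expressed targets receive a −3 Ct case shift
  (≈ 8-fold increase). References are generated with zero effect and
  σ = 0.1; spike-ins sit exactly log2(1000) cycles apart with σ = 0.15.
- **Tissue**: duplicate mutant lysates over the serum panel plus U6
  (appended, keeping the serum and tissue assay universes aligned);
  expressed fraction 0.625 with baselines [24, 42] so the detected union
  across duplicates lands near the mid-400s; U6 at Ct 22, σ = 0.1;
  spike-ins are *not* spiked into lysates and generate as undetected. Each
  serum-increased assay is redrawn from the abundant stratum ([24, 27] Ct)
  with probability 0.5, which puts roughly half of them in the top-100
  tissue ranks — the study-like regime.
- **qPCR**: 16 targets, 9 mutant vs 10 wild-type samples, σ = 0.4; 3
  targets shifted by −1.5 Ct in mutants.

Ground truth records baselines, effects, offsets, per-assay noise and the
noise-free expected Ct per well, from which closed-form detection
probabilities `Φ((lod − mean_Ct)/σ)` are available; the suite checks
realized detection counts against them. Generators are pure functions of
(config, seed).

What the generator does **not** emulate: biological inter-mouse variance
beyond a global offset (real effect sizes vary per animal), hemolysis and
blood-cell contamination signatures, amplification-efficiency differences
between assays, stochastic dropout near the limit of detection, and any
correlation structure among miRNAs. Passing tests therefore demonstrate
that the pipeline's statistics behave correctly under its stated model —
not that the model captures everything real serum data do.

## Clustering and separation score

Samples are clustered on log2 quantities with 1 − Pearson correlation
distance (default; Euclidean available) and average linkage (complete
available) — conventional defaults for expression heatmaps. Assays with
any undetected value are excluded from the distance computation; an
explicit assay subset is sorted by name first, so output is deterministic.
Artifacts are text: a Newick dendrogram and the column-reordered matrix.
The separation score operationalizes "the groups form distinct clusters":
the fraction of samples whose cophenetically nearest neighbour shares
their group label (ties broken by sample name), 1.0 meaning perfectly
label-concordant neighbourhoods. It is invariant under relabelling and
undefined (raises) for a single group.

## Pipeline and reproducibility

`run_pipeline` chains simulate/load → detection filter → both
normalizations → differential tables → consensus + kappa → clustering, and
writes every stage's output as delimited text plus a key-value
`run_metadata.txt` recording seed, thresholds, contrast, methods and the
headline results. Stage failures propagate with the stage name attached.
Reruns with the same config and seed produce byte-identical numeric
outputs (checked by checksum in the suite).

## Problem sizes in the checks

The statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the tolerance being checked: the null type-I-error check
uses 1,000 assays (99% binomial band ±1.8 percentage points around
α = 0.05); fold-change bias uses 200 perturbed assays per effect size at
n = 6 vs 6 (standard error ≈ 0.03 against a 0.2 tolerance); the
hypergeometric top-N check averages 100 tissue generations. Point checks
whose single-draw sampling error is comparable to their stated tolerance —
the qPCR fold-change recovery within 15% at n = 9 vs 10, the ±0.5 log2
fold-change window at n = 3 vs 6 — are asserted on means over injected
assays or replicate datasets rather than on individual draws, with the
tolerances unchanged.

## Known limitations

- The variance-stabilizing scheme is a specified approximation, not a
  maximum-likelihood glog fit; with few samples and a half-detected panel
  the two can rank borderline assays differently.
- Welch's test at n = 3 vs 6 has approximate size; the suite verifies the
  realized type-I error empirically rather than assuming it.
- No multiple-testing correction is applied (by design, for fidelity to
  the workflow being implemented); consensus intersection reduces but does
  not eliminate shared false positives, since both methods see the same
  noise.
- Only two-group contrasts are supported; multi-group designs compose
  pairwise runs.
- Undetected values are never imputed; assays partially detected in a
  contrast's samples are dropped from testing rather than analysed with
  censored-data methods.
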