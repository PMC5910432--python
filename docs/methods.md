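# Methods

Statistical definitions, generator constructions, parameter defaults and
numerical choices for `ffpeqc`. All computations are deterministic: the same
inputs (and, for simulators, the same seed) produce byte-identical output.

## 1. RNA quality from electropherograms

### DV200

An electropherogram is a fluorescence-vs-fragment-size trace
(`size_nt`, `fluorescence`), with sizes strictly increasing and fluorescence
non-negative. DV200 is the percentage of the trace area above 200 nt:

    DV200 = 100 · A(>200 nt) / A(total),

with areas computed by trapezoidal integration over the *analysis window*,
default (25 nt, ∞). The lower bound excludes the chip's internal marker
spike, which sits at ~25 nt and would otherwise deflate DV200. Both the
window edge and the 200 nt boundary are handled exactly: if no grid point
falls on them, a point is inserted by linear interpolation so that no
trapezoid straddles either cut. A trace with zero total area inside the
window has no defined DV200 and raises `UndefinedMetricError` rather than
returning 0 or NaN.

### Quality categories

DV200 maps to a category:

| DV200 | category |
|---|---|
| > 70 | high |
| 50–70 (inclusive) | medium |
| 30–50 (exclusive of 50) | unassigned |
| < 30 | low |

The 30–50 band is deliberately left *unassigned*: the source thresholds name
only the three outer bands, and silently extending one of them would change
downstream triage decisions. Callers that need a binary usable/unusable call
should apply their own rule to the numeric DV200.

### Cross-link (high-molecular-weight) peak

Formalin cross-linking can produce a spurious high-molecular-weight peak in
FFPE traces. `detect_high_mw_peak` searches a window (default 2 500–5 000 nt)
for a local maximum whose height exceeds

- `prominence_factor` (default 2.0) × the median fluorescence *outside* the
  window, and
- `min_rel_height` (default 0.02) × the trace maximum.

The second guard suppresses numerically tiny ripples on near-zero plateaus
that would otherwise pass the median test when the outside-window median is
itself almost zero. **Interpretation caveat:** the detector is geometric and
does not know about rRNA; in an intact (fresh-frozen) trace the 28S rRNA
peak (~4 700 nt) falls inside the default window and will be flagged. The
call is meaningful only for degraded FFPE traces, where intact rRNA peaks
are absent.

## 2. Reproducibility metrics

### Per-gene %CV

For each gene, across the replicates of one group,

    %CV = 100 · sd / mean

computed on the **linear** intensity scale (log2 matrices are exponentiated
first) with the sample standard deviation (n − 1 denominator). Groups need
at least two replicates. `%CV` is scale-invariant, so it can be compared
across platforms with different overall intensity.

### Comparing %CV distributions

`cv_compare` applies a cube-root transform to both %CV sets (the transform
symmetrises the right-skewed %CV distribution), then runs an unpaired
two-tailed equal-variance t-test and reports Cohen's d (mean difference over
pooled standard deviation) alongside t, df and p.

### Pearson correlation and clustering

Sample–sample Pearson correlation is computed on log2 intensities. A sample
with zero variance has no defined correlation and raises
`UndefinedMetricError`. Intra-group values are averaged over distinct sample
pairs within a group; inter-group values over all cross pairs. Hierarchical
clustering is UPGMA (average linkage, `scipy.cluster.hierarchy.linkage`)
on the distance 1 − r. Samples are pre-sorted lexicographically before
linkage so that the result is invariant to input column order; dendrograms
export to Newick.

### 3′/5′ ratio

For each gene with probe sets at positions 1…k (5′ → 3′),

    ratio = log10(signal at position k / signal at position 1).

Positive values indicate 3′ signal excess, the signature of degraded RNA
with oligo-dT-primed targets. Genes with a single position are excluded
(and counted), not errors; non-positive signals are rejected. The statistic
is antisymmetric under position reversal.

## 3. Concordance of relative expression

### Replicate-ratio concordance

Within each group, for basis replicate b, each other replicate j yields a
per-gene fold-change ratio r_j = x_j / x_b. A pair of ratios (one from each
dataset) is **concordant at cut-off c** iff

- both lie in the closed interval [1/c, c], or
- both are > c, or
- both are < 1/c.

Default cut-offs: 1.3, 1.5, 1.7, 2.0. Under the default `"all"` aggregation
a gene counts as concordant for basis b only if *every* replicate pair
matches; `"per_pair"` instead averages over pairs and is never stricter.
The per-basis rate is the percentage of concordant genes; the overall rate
is the mean over bases. Note the statistic is **not monotone in c**: the
pair (1.6, 3.0) is discordant at c = 2.0 (one inside, one outside) but
concordant at c = 1.5 (both above).

### Group-mean concordance

The same match rule applied to case/control mean ratios computed on two
platforms; gene sets are intersected first.

### Top-N rank comparison

Genes are ranked by group mean expression (rank 1 = highest); ties are
broken lexicographically by gene id so ranks are deterministic. For the top
N (default 100) genes of dataset A, counts are reported in bins: still in
the top N of dataset B, rank difference ≤ 400, rank difference > 400 (bin
edges configurable; bins partition the N genes).

### ΔCq ranking and Cq summaries

For a qPCR panel with a designated reference gene,
ΔCq = mean reference Cq − mean gene Cq, so higher ΔCq means more abundant;
rank 1 is the most abundant gene. Cq summaries report the geometric mean
(exp of the mean log Cq) ± the sample standard deviation on the Cq scale.

### Differential-expression filter

Per gene: an unpaired two-tailed t-test on log2 signals (equal-variance
pooling by default, Welch optional) plus a signed linear fold change
(down-regulation encoded as −1/ratio). Selected iff |FC| ≥ 2 and p ≤ 0.05
(both configurable). No multiple-testing correction is applied — the filter
reproduces the common FC + p screen, and its output should be treated as a
screening list, not inference. Genes with zero variance in both groups have
an undefined t statistic; they get NaN t/p and a `degenerate` flag instead
of a spurious call.

## 4. Synthetic-data generators

All generators take a seed and use `numpy.random.default_rng`. They are
*stylised*: each produces the minimal structure needed to exercise and
validate the corresponding metric, not a physically faithful instrument
model.

### Paired expression matrices

`simulate_expression_pair` draws per-gene base levels from
Normal(`base_log2_mean` = 7, `base_log2_sd` = 2) on the log2 scale, then adds
i.i.d. replicate noise with `noise_sd_a` = 0.15 (FF-like) and
`noise_sd_b` = 0.35 (FFPE-like). The defaults were fixed a priori to give an
intra-group Pearson r around 0.97–0.99 and a roughly twofold median-%CV gap,
the qualitative FF/FFPE regime. A fraction `frac_discordant` of genes gets
±log2(`fc_injected`) added to replicate 2 — positive in dataset A, negative
in dataset B — creating genuine relative-expression discordance while
leaving group means nearly unchanged. A truth table records which genes were
perturbed. `group_offset_log2` adds a constant platform offset, which the
ratio-based statistics must (and do) ignore.

### Electropherogram traces

The FFPE profile is a gamma-density smear (shape 2, scale 250 nt — mode
250 nt, right tail into the kilobase range) on a 25–6 000 nt grid (5 nt
step). To hit `target_dv200` exactly in the noiseless case, the part of the
curve below 200 nt is multiplied by a factor α solved in closed form from
the trapezoid areas, with the boundary trapezoid split at 200 nt so the
rescaled trace integrates to the target exactly (target 100 zeroes the
below-boundary part). An optional `crosslink_peak` adds a Gaussian bump
(default off); the DV200 rescaling is applied after, so the target still
holds. The FF profile is a low gamma background plus Gaussian rRNA peaks,
default (1 900 nt, height 1.0) and (4 700 nt, height 2.0) for 18S/28S.
Noise is multiplicative (`noise_sd` × N(0,1) relative), preserving zeros.

### Exon-level tables and Cq tables

`simulate_exon_table` gives each gene a log10 base level and a linear ramp
of slope `gradient_log10` across probe-set positions, plus Gaussian log10
noise — so the noiseless 3′/5′ ratio equals the gradient exactly.
`simulate_cq_table` draws base Cq values uniformly in (18, 30) and returns
an FF table and an FFPE table shifted by `ffpe_offset_cycles` (default 5)
plus noise, reflecting the input-loss cycle delay of FFPE templates.

## 5. Numerical and I/O choices

- Integration is trapezoidal throughout; boundary/window points are inserted
  analytically rather than approximated by grid refinement.
- t-tests, linkage and distributions come from scipy; correlations from
  numpy. Hand-rolled numerics are limited to the primitives the package is
  about (DV200 splitting, match rules, α rescaling).
- Text files round-trip exactly: floats are written with Python repr
  precision and parsed with pandas' `round_trip` parser, so
  write → read → write is byte-identical.
- The pipeline writes `summary.json` with sorted keys and fixed rounding;
  identical configs and seeds yield byte-identical report bundles.

## 6. Limitations

- Generators model neither probe-level effects, normalisation (e.g. RMA),
  batch structure, nor realistic fragment-size distributions; they validate
  the metrics, not instrument physics.
- The cross-link detector flags any prominent high-MW peak, including 28S
  rRNA in intact traces (see caveat above).
- Concordance rates are not monotone in the cut-off by construction.
- The DE filter performs no multiple-testing correction and, with the
  default 3 + 3 replicates, has low power; it is a screen.
- The quality category map leaves DV200 in [30, 50) unassigned by design.
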