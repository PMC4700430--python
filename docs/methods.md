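# Methods

This note records the statistical models, conventions and design
choices behind `bloodtx`, in the order the pipeline applies them, plus
what the synthetic-data generator does and does not emulate.

## Preprocessing model

Raw single-color intensities are floored at `raw_floor` (default 1.0)
before log2, so the transform is always defined and the log scale has a
zero minimum.  Normalization is a per-sample 75th-percentile shift:
each column's 75th percentile of log2 signal is subtracted, making
arrays comparable under the assumption that the bulk of the intensity
distribution is stable across samples.  The baseline transformation
then centers each probe at its median over all samples; this is a
display/clustering convenience that provably leaves every between-group
mean difference (hence every fold change) unchanged.

All percentiles use linear interpolation between order statistics.

Two filters follow.  The expression filter summarizes each probe by its
**median across samples of the shifted (normalized, pre-baseline)
values** and keeps probes whose summary strictly exceeds the
`filter_percentile` (default 20th) percentile of all summaries.  The
summary is computed pre-baseline because baselining forces every
row median to zero and would erase the signal-level information the
filter needs.  This per-probe reading of "20th percentile threshold" is
one defensible convention among several; it is recorded in the filter
report so users can audit it.  The flag filter keeps probes called
present or marginal in at least `min_fraction_present` (default 1.0) of
the samples of at least one diagnostic group, mirroring the common
vendor default of "100% of samples in any one condition"; a pooled
`all_samples` scope is available.  Filters only remove rows — surviving
values are never altered — and the whole chain is deterministic.

## Moderated t

Per probe the unpaired two-group statistics are computed on the log2
scale: group means, their difference (log2 fold change), and the pooled
variance s² with df = n₁+n₂−2.  Across probes, s² is modelled as drawn
from a scaled inverse-chi-square prior with hyper-parameters (d₀, s₀²),
estimated by matching the first two moments of log s² to the implied
log-F distribution (digamma/trigamma inversion, Newton iteration for
the trigamma inverse).  When the observed spread of log s² does not
exceed what pure sampling noise implies, d₀ is reported infinite and
all probes share s₀²; when every s² is exactly equal the common value
is returned directly.  The moderated statistic uses the posterior
variance s²_post = (d₀s₀² + df·s²)/(d₀+df) with df_total = df + d₀
(normal reference when d₀ = ∞).  The d₀ → 0 limit recovers the ordinary
pooled t exactly.  A test cross-checks the whole path — prior fit, t,
p — against the Bioconductor `limma` implementation on a small matrix.

The analysis is **unpaired by default** even though samples are matched
pairwise: the matching controls confounders at the design level, and
the group-comparison framing keeps fold changes interpretable as
between-group ratios.  A paired variant (one-sample moderated t on
within-pair differences) is available via `paired=True` / `--paired`.

Thresholds are strict: DEG selection requires p < `p_max` (default
0.01) **and** |signed FC| > `fc_min` (default 1.5).  No multiple-testing
correction enters selection — the design goal is a relatively large DEG
set for downstream pattern analyses, and adjusted p-values are emitted
in a reference column only.  Signed fold change is the display
convention signed_fc = 2^lfc for lfc ≥ 0 and −2^(−lfc) otherwise, so
its magnitude is always ≥ 1.

## Overabundance

The curve compares O(α) = #{pᵢ ≤ α} (non-strict, so O(1) = N) with the
uniform-null expectation αN over a default grid of 100 log-spaced
thresholds from 10⁻⁴ to 1.  The permutation band re-runs the full
moderated-t computation (prior refit included) under random group
relabellings; by default labels are swapped independently within each
matched pair, honoring the paired design (2¹⁴ possible relabellings at
14 pairs); free permutation is available.  The band records per-α
2.5/50/97.5% quantiles over B permutations (B ≥ 100 recommended;
smaller B warns) and is deterministic given the seed.

## Separation

PCA treats samples as observations and centers but does not rescale
probes — after baselining the values are already on a common log-ratio
scale, and unit-variance scaling would up-weight the noisiest probes.
Clustering is UPGMA (average linkage, Euclidean distance) cut at two
clusters; merge ties follow the deterministic lowest-index convention.
Cluster accuracy is the better of the two cluster↔group assignments, so
chance level is 0.5.  "Linear separability" is made concrete as the
resubstitution accuracy of the best linear boundary in the PC1–PC2
plane, found exactly by enumerating candidate boundary directions
parallel and perpendicular to every segment between two sample points
and scanning all thresholds; cuts are only allowed between strictly
different projections, since no linear boundary separates coincident
points.  Above 200 samples the enumeration cost is no longer justified
and a linear-discriminant boundary is used instead (noted in output).

## Candidate-gene enrichment

Candidate symbols are matched to probe annotation case-insensitively
after whitespace stripping.  The exceedance table counts probes (not
genes) whose |signed FC| strictly exceeds the cutoff.  Two
constructions are provided: `printed` keeps the candidate probes inside
the comparison ("all probes") column — the way such ratio comparisons
are typically printed — and `disjoint` removes them for a clean
partition; on realistic counts the two chi-squares differ by a few
percent, and tests document the agreement numerically.  The chi-square
is Pearson's without continuity correction (Yates' correction available
by flag, noticeably more conservative on tables of this shape).  The
generic gene-set test is a hypergeometric upper tail on the
in-background portion of each set with Benjamini–Hochberg adjustment
across sets; it is a self-contained substitute for interactive pathway
portals, using user-supplied GMT collections.

## Co-expression networks

All C(m,2) candidate-probe pairs are correlated within each group with
Spearman's rho (mid-ranks for ties; constant probes yield missing
values, tallied separately and excluded from counts).  Significance
uses the t approximation t = ρ√((n−2)/(1−ρ²)), df = n−2, rather than an
exact permutation null: at the design's group size (n = 14) the
approximation reproduces the familiar correspondence ρ ≈ 0.97 ↔
p ≈ 10⁻⁸, and the exact null would add real cost for no qualitative
change; an exact option is noted as future work.  `rho_threshold`
inverts the significance function by bisection to 10⁻⁶.

Pair counts use strict p < α.  Graph construction additionally drops
edges whose two probes map to the same gene symbol (probe redundancy,
not co-regulation); this suppression applies to graphs and hub counts,
not to the raw pair counts, and the choice is recorded in the output.
An optional gene-collapsed graph merges multi-probe genes keeping the
union of edges.  Hubs are nodes at or above a degree threshold (default
6).  The Shapiro–Wilk screen (per probe, per group, α = 0.05) documents
the prevalence of non-normal probes that motivates the rank
correlation.

## Synthetic data

The generator emulates a matched case-control one-color microarray
study on the log2 scale:

    signal(g, s) = baseline_g + de_effect_g·[s case]
                   + loading_{group(s)}·f_s + ε,    raw = 2^signal

with baseline_g ~ N(8, 1.5²), ε ~ N(0, 0.5²), and one latent factor
f_s ~ N(0,1) per sample shared by the module probes.  Defaults define
the study design: 14 pairs, 5,000 probes (44,000 approximates a full
array but is unnecessary for validating the machinery), 20%
low-expression probes sitting just above the raw floor and flagged
absent, 100 DE probes with |log2 FC| uniform on [0.7, 1.5] (|FC|
1.62–2.83) and random sign, and a 20-probe module inside a 169-gene
candidate list with loadings 0.9 (controls) vs 0.1 (cases) — the
reduced case loading is the simplest mechanism that produces fewer
significant correlations in patients.  Candidate genes outside the
module sit on well-expressed *null* background probes, so candidate
status and differential expression are independent by construction;
every fifth extra candidate gene carries two probes to exercise
same-gene edge handling.  A null variant sets n_de = 0 and equalizes
loadings for calibration tests.

With the default noise, the planted module's pairwise Pearson
correlation in controls is 0.81/(0.81+0.25) ≈ 0.76 — comfortably
significant at p < 0.01 with n = 14 but far below the ρ ≈ 0.97 needed
at the stringent 10⁻⁸ display threshold.  Tests of network recovery at
that threshold therefore use a low-noise variant (loading 0.95, noise
0.1) where the module correlation ≈ 0.99 by construction; this is a
property of the threshold, not a defect of the estimator.  Likewise,
the planted disruption is assessed on the module probes' pairs: across
all C(199,2) ≈ 19,700 candidate-probe pairs the ~190 module pairs are
diluted by null pairs whose false-positive counts are identical in both
groups, shrinking any count ratio toward 1 regardless of effect size.

What the generator does **not** emulate: probe sequences and
cross-hybridization, spatial array artifacts, batch and hybridization
date effects, dye chemistry, correlated background co-expression
outside the single module, age/sex effects on expression, and
heavy-tailed biological outliers.  Passing recovery tests therefore
demonstrates that the machinery is correct and well calibrated under
the stated generative model — not that real blood expression data will
separate this cleanly.

## Problem sizes and numerics in the test suite

Routine tests run on 300–1,000-probe datasets; the stochastic recovery
suite uses 20 replicates of the default 5,000-probe design and a
10,000-probe variance-prior recovery, chosen so the full suite
completes in well under a minute on one CPU while keeping Monte-Carlo
error small relative to the asserted margins (median sensitivity ≥ 0.8,
false-discovery proportion ≤ 0.2, disruption ratio > 2, d₀ within
±25%).  Numerical conventions: percentile interpolation is linear;
p-values are clipped to a 10⁻³⁰⁰ sentinel floor (degenerate
zero-variance probes and |ρ| = 1 report the sentinel with a warning);
bisection tolerance for rho thresholds is 10⁻⁶; top-table ties break by
|FC| descending then probe id; dendrogram and boundary-search
tie-breaks are deterministic so reruns are byte-identical.

## Known limitations

- Gene-level summarization across probes is limited to the optional
  collapsed co-expression graph; DE stays probe-level.
- No covariate adjustment (age, sex, cell composition) — the matched
  design is the only confounder control.
- The permutation band at 14 pairs draws from only 2¹⁴ distinct
  relabellings; with B = 200 duplicate draws are common but harmless.
- The Spearman p-values are asymptotic; at n ≪ 10 per group the t
  approximation becomes rough.
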