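# Methods

This note documents the statistical procedure implemented by `nmatransit`,
its assumptions, defaults and the design decisions taken where the procedure
left genuine freedom.

## Dissimilarity model

The unit of analysis is the *comparison-level observation*: a study with
$T$ arms is expanded into $\binom{T}{2}$ rows that inherit the study's
characteristic values, so a network of $N$ studies yields an
$\sum_i \binom{T_i}{2} \times \sum_i \binom{T_i}{2}$ pairwise matrix
$\{d\}$. Rows of one multi-arm study are exactly zero-dissimilar (they are
the same study) and are forced to 0 in the matrix.

Pairwise dissimilarity is the weighted Gower coefficient over mixed-type
characteristics with a missingness indicator $\delta_{xy,i}$: a pair is
compared only over co-observed characteristics, and a pair sharing none is
*undefined* — it is flagged and excluded from downstream aggregation with a
warning, never silently set to zero. No imputation is attempted; with the
typical extraction-table missingness of a few percent, the $\delta$ rule
loses little information, but users should expect instability when
characteristics are missing for most studies.

Normalising ranges:

* quantitative $R_i$ — observed min–max over *studies* (expansion only
  duplicates values, so study-level and row-level ranges coincide; the
  study-level definition makes the semantics explicit). A user-supplied
  `range` in the configuration overrides the observed range, which is the
  recommended guard when the observed spread is narrow relative to the
  review's inclusion criteria or driven by one outlying study.
* ordinal $RR_i$ — range of the integer codes (declared level order) that
  actually occur in the data.
* A quantitative characteristic constant across all studies has $R_i = 0$;
  it contributes $d_i = 0$ for every pair (all studies agree) and a warning
  is emitted. A zero range combined with unequal values is an error.
* Binary characteristics are nominal with two levels.

Weights: each characteristic defaults to weight 1; the members of a
`summary_group` (several summary statistics of one underlying quantity)
have their weights renormalised to sum to one, so the underlying
characteristic contributes a total weight of one. The coefficient is
invariant to a global rescaling of the weights.

## Comparison-level aggregation and classification

$D_p^W$ and $D_{pp'}^B$ are root mean squares *about zero* (population
form): the intent is spread from complete similarity, not from the average
dissimilarity. A single-study comparison has $D_p^W = 0$. Cross pairs of
$D_{pp'}^B$ that originate from one multi-arm study informing both
comparisons are included with their zero value — they are genuine elements
of the designated block of $\{d\}$ — and their count is carried in the
`n_pairs` provenance matrix.

Thresholds of "low" dissimilarity are the medians of empirical predictive
distributions of $I^2$ for a future meta-analysis, indexed by outcome type
(all-cause mortality / semi-objective / subjective), comparator type
(pharmacological vs placebo-control / pharmacological vs pharmacological /
non-pharmacological) and average study size (<50 / 50–200 / >200
participants), with 0.13 for the general healthcare setting. The size bucket
is derived from the unweighted mean of study total sample sizes. The
classification rule is strict: a value exactly equal to the threshold is
*likely concerning*. The full 3×3×3 grid plus the general entry is encoded
in `nmatransit.comparison.THRESHOLDS`; the choice among them is the user's
(no automatic inference of outcome type is attempted).

## Clustering and model selection

Agglomeration runs on $\{d\}$ via the standard Lance–Williams updates
(scipy) for seven linkage methods: average, complete, single, weighted,
ward, centroid, median. Ward operates on the usual squared-distance update;
since Gower dissimilarities are not Euclidean, Ward, centroid and median are
heuristics here — centroid/median may produce height inversions, which are
flagged but retained, and tree cutting is by cluster count, so inversions do
not break cuts.

The linkage is chosen by the highest cophenetic correlation coefficient.
Exact CCC ties are broken by a fixed preference order
(average > complete > single > weighted > ward > centroid > median) for
reproducibility; a seeded random tie-break is available
(`random_state` / `--seed`) for users who prefer the randomised convention.

The partition is chosen by the overall average silhouette width over cuts
$k = 2,\dots,n-1$ (sklearn's standard formulation on the precomputed matrix;
members of singleton clusters score 0). Besides the arg-max, the first three
local optima of the profile are reported, since a near-tied coarser
partition is often the more interpretable choice; exact arg-max ties resolve
to the smaller $k$.

A comparison is *fragmented* when its rows span two or more clusters;
its *eloping* percentage is the share of rows outside its modal cluster.
The report attaches a coarse severity tag: `none` (no fragmentation), `a`
(two-to-three clusters, eloping shares at or below the 5% default — the
minimum acceptable eloping share), `b` (two clusters, fragmentation limited
to at most half the comparisons), `c` (two clusters, widespread
fragmentation), `d` (more than two clusters with fragmentation). The tag
is a reading aid, not a verdict; the per-comparison percentages are always
reported.

## Synthetic data

`generate_network` plants a cluster structure: cluster $c$ centres
quantitative characteristic $c \bmod n_{quant}$ at `shift` (in within-cluster
standard-deviation units, sd = 1) and the rest at 0, and prefers its own
category level with odds $(1+\text{shift})^2$. This one-informative-dimension
geometry keeps all cluster pairs comparably separated after Gower's range
normalisation, so `shift` behaves as a single interpretable separation knob:
0 removes all signal, 3 gives strong separation, and recovery of the planted
$k$ by the silhouette profile is the generator's calibration target.
Defaults — 24 two-arm studies on a three-treatment star, ten characteristics
(five quantitative, five nominal with `max(3, k)` levels), no missingness —
emulate a modest systematic-review extraction table. Missingness is applied
completely at random only; informative missingness, arm-level
characteristics and outcome/effect data are out of scope, so passing the
recovery tests says nothing about networks whose heterogeneity lives in
unextracted or systematically missing characteristics.

The packaged rheumatoid arthritis and COPD fixtures are **synthetic
stand-ins**: they reproduce every structural property documented for the two
published extraction tables they emulate (network shape, per-comparison
study counts, arm structure, characteristic types and weights, and the COPD
missing-cell pattern — 30 of 847 expanded cells, 3.54%, with 6–7 rows per
affected characteristic), while the values themselves are simulated from
plausible clinical ranges under a fixed seed. Dissimilarity magnitudes
computed from them are therefore properties of the stand-ins, not of the
published datasets. The 7-study fictional triangle's values are likewise this
package's own, chosen once to satisfy the intended qualitative pattern
(one large/young/adequately-randomised comparison, one small/old/inadequate,
one intermediate) and frozen.

## Numerical choices and problem sizes

* Oracle tests compare the vectorised Gower matrix, the RMS aggregations and
  the silhouette widths against naive reference implementations at 1e−12.
* Undefined (all-$\delta$-zero) pairs propagate as NaN with a mask; the
  clustering entry point refuses matrices containing them.
* The recovery experiment uses 50 generator replicates per condition
  ($k \in \{2,3,4\}$ at shift 3, plus a shift-0 null), a size at which the
  whole experiment completes in well under a minute while the binomial
  uncertainty on a 90% recovery rate is ~4 points.
* Report rendering is deterministic given identical inputs; the JSON summary
  rounds floats to 10 decimals to make byte-identical reruns meaningful.

## Known limitations

* Characteristic weights are user-supplied, not estimated; beyond the
  summary-group rule there is no guidance on differential weighting.
* The $I^2$-based thresholds are a pragmatic transplant from the statistical
  heterogeneity literature; dissimilarities and $I^2$ share only their
  range, not their sampling behaviour.
* Gower's observed-range normalisation makes quantitative contributions
  sensitive to outliers and to restriction of range (use `range` overrides).
* Purely textual eligibility information cannot enter the metric.
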