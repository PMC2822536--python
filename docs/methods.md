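# Methods

This note documents the statistical model behind `bimodal-expr`, the
parameters that matter, the numerical conventions, and the limits of what
the synthetic-data tests demonstrate.

## The partition model

Each gene is treated independently. Its M signals (one per sample,
continuous, assumed log-scale-like so that within-mode noise is roughly
additive) are sorted and split into a lower subset L (the k smallest
values) and an upper subset U, for every k from 1 to M−1; splits with an
empty subset are not admissible (a one-sided "partition" carries no
bimodality information). The split minimizing the total within-subset sum
of squared deviations γ = SS(L) + SS(U) is the 1-D two-means optimum, found
by an O(M) scan over centered prefix sums after an O(M log M) sort. Ties in
γ resolve to the smallest k, so results are order-stable and reproducible.

The subset means l = ⟨L⟩ and u = ⟨U⟩ anchor the two modes, and the
threshold T = (max L + min U)/2 is the midpoint of the boundary signals —
strictly between the modes, and exactly 0 after normalization. The
separation statistic is

    tau = (u − l) / sqrt(γ / M).

Both the numerator and the denominator scale linearly under x → a·x + b
(a > 0), so tau is affine-invariant: platform-specific intensity scalings
and offsets do not change it. For a single Gaussian the optimal split sits
at the mean, the two halves are half-normals with means ±σ·√(2/π) and
common variance σ²(1 − 2/π), giving the asymptotic null baseline

    tau_normal = 2·sqrt(2/π) / sqrt(1 − 2/π) ≈ 2.6472

(exported as `NORMAL_BASELINE_TAU`). Because the split is *optimized on
the sample*, finite cohorts overfit slightly: the null mean of tau lies a
few hundredths above 2.6472 at M of a few hundred and approaches it from
above as M grows (the test suite measures this directly). Consequently the
conventional cutoff tau > 2.64 sits essentially at the null mean: it is a
deliberately liberal first-pass filter that admits roughly half of
single-Gaussian genes, not a 5 %-FPR test. Specific calls are expected to
be sharpened by the companion variance filter and, above all, by the
close-neighbors grouping step, which unrelated false positives do not
survive. Interpret `is_bimodal` accordingly.

## Outliers

A handful of extreme signals would otherwise claim a whole "mode" (e.g. 3
very high values out of 100). If the optimal partition's smaller subset
holds fewer than `outlier_fraction` (default 0.05) of the *original*
signal count, its values are flagged as outliers, removed, and the
remainder re-partitioned; this repeats until both subsets are large enough
or the remainder degenerates. The fraction is measured against the
original n so that repeated trimming cannot erode more than the rule
intends. Fewer than 4 surviving values is an error (flagged, not raised,
in batch detection). Setting the fraction to 0 disables the rule. The
trim is idempotent: once a pass removes nothing, further passes cannot.

## Variance filter

tau is scale-free, so a second, scale-aware criterion guards against genes
whose "modes" are analytically separable but biologically negligible: a
gene must also have per-gene sample standard deviation (n−1 denominator,
missing values dropped) strictly above the `std_percentile` (default 25th,
linear-interpolation) percentile of the cohort's per-gene std
distribution. Both comparisons (tau and std) are strict, so degenerate
all-equal distributions pass nothing.

## Normalization and orientation

Bimodal genes are mapped onto a common ±1 scale by the strictly increasing
piecewise-linear transform hinged at T:

    x ≤ T:  (x − T) / (T − l)        x > T:  (x − T) / (u − T)

so that l → −1, T → 0, u → +1 exactly (bit-exact anchor identities; a
single linear map could not honor all three anchors unless T were the
midpoint of l and u). Values outside [l, u] map beyond ±1 and are *not*
clipped — consumers who want hard binarization can clip or take signs.
Since (l, T, u) transform covariantly under positive affine distortions,
normalized profiles are platform-independent to rounding error; this is
tested to 1e-9.

With control/normal samples, each gene's controls are required to fall on
one side of T: all on the +1 side, keep as-is; all strictly below T, flip
the gene's sign so the control mode reads +1; controls on both sides make
the gene unorientable and it is excluded (values set to missing). A
control value exactly at T counts as the upper side, matching the
barcoding convention below. Without controls the upper mode is +1.

## Close-neighbors groups

Distances between normalized profiles use the cosine distance
ρ = 1 − x·y/(‖x‖‖y‖) ∈ [0, 2] over the shared non-missing samples.
Co-regulated bimodal genes have near-parallel ±1 profiles (ρ near 0);
unrelated bimodal genes have independent mode patterns (ρ concentrated
around 1). A group around a query gene exists when the distance
distribution shows an isolated cluster near zero, separated from the bulk
by an empty gap — and absence of a group is a normal outcome, not an
error.

The gap rule ("gap" strategy, the default): distances from the query to
all other normalized genes (the trivial self-distance excluded) are binned
over [0, 1] with `bin_width` 0.05; leading empty bins are skipped; the
cluster runs from the first populated bin to the first run of
`min_gap_bins` (default 2) consecutive empty bins; and the gap must open
below `median_factor` (default 0.5) times the median distance. The 2-bin
gap requirement makes the rule robust to single empty bins inside a sparse
cluster of a handful of genes, and the half-median guard rejects "clusters"
that are merely the left tail of the bulk. A "fixed" strategy (all genes
with ρ ≤ 0.25) is available as a simpler fallback. Anti-correlated
partners (ρ near 2) are not added by default — after control-based
orientation, co-regulated genes point the same way — but
`include_anticorrelated=True` folds the distance scale (d → min(d, 2−d))
and records such members as sign-flipped.

The group profile is the per-sample mean of members' normalized values
(flipped members negated); members absent from a dataset (not assayed on
that platform) are simply skipped, so a group remains usable across
platforms with incomplete gene complements. Barcodes read the sign of each
group profile per sample: code 1 when negative, 2 when ≥ 0 (exactly 0 reads
as the high mode; the boundary convention is arbitrary but fixed). With G
groups the barcode partitions the cohort into at most 2^G clusters; group
order is the caller's.

## Meta-analysis

Pairwise dataset comparisons restrict both bimodal sets to the genes
present on both platforms (genes absent from a platform are "not assayed",
never "not bimodal") and score the overlap with the one-sided
hypergeometric upper tail P(X ≥ overlap) — the over-representation reading
of the Fisher exact test, and the only one consistent with enrichment
magnitudes; a two-sided option sums all point masses no more likely than
the observed one. Tails are accumulated with `logsumexp` over log point
masses so p-values at magnitudes like 1e-112 are computed without
underflow; an exhaustive small-universe test checks the log-space tail
against direct summation. For annotation enrichment the universe is a
user-supplied constant (default 40599, a genome-wide gene count) rather
than the platform size, since annotation sets are genome-wide objects.
"Commonly bimodal" genes are those called in at least `min_datasets`
(default 3) of the supplied datasets; gene matching across datasets is
case-insensitive symbol identity (no probe/ID translation service).

## Synthetic cohorts

The generator produces the structure the pipeline assumes, with ground
truth. Defaults describe a typical desk-scale study: 2,000 genes × 200
samples, 10 % bimodal, within-mode σ = 0.5 around N(7, 1) baselines (log2
intensity scale), mode separation delta = 6 (in units of σ; the decisive
quantity — σ itself cancels out of tau and of the normalized scale),
balance 0.5, five planted groups of ~5 genes whose members follow a shared
per-sample Bernoulli latent mode with 95 % agreement, no injected
outliers. Each additional platform re-observes the *same* underlying
cohort through an independent per-gene positive affine distortion
(log-normal scale, Gaussian offset, spread `affine_jitter`) — the minimal
model of cross-platform intensity differences, and exactly the
transformation class tau and the normalization are invariant to. Optional
control samples draw every bimodal gene from one designated mode
(default the lower, as normal tissue against disease-activated genes).
All randomness flows from one seed through a single generator, so
identical configs reproduce identical matrices.

What the generator does *not* emulate: probe-level array physics
(saturation, background), correlated noise across genes, batch effects
beyond affine distortion, unbalanced missingness, splice variants, or real
biological pathway structure. Passing the planted-recovery tests therefore
demonstrates the pipeline's correctness under its own model assumptions,
not performance on raw public array data, which would additionally require
the usual preprocessing (background correction, summarization,
normalization) outside this package's scope.

## Numerical conventions and degenerate inputs

- Partition scan uses centered prefix sums; γ is clamped at 0 against
  rounding. γ = 0 with u > l yields tau = +inf (serialized as "inf").
- All-identical signals: degenerate, flagged `degenerate` in batch calls.
- Fewer than `min_samples` (default 10) non-missing values: flagged
  `insufficient_data`. The guard is this package's own; typical cohorts
  (hundreds of samples) never hit it.
- Duplicate gene ids at parse time collapse to the maximum-variance row by
  default (the most informative probe); "mean" and "error" are available.
- Missing cells ("", "NA", "NaN") are tolerated everywhere and dropped
  per-gene; cosine distances use the pairwise-complete sample set.
- The tau threshold (2.64), std percentile (25), outlier fraction (0.05)
  and min_datasets (3) defaults follow the conventional settings for this
  method; every CLI output embeds the effective parameters in a `#` header.

## Known limitations

- The bimodal call controls no error rate; see the discussion of the null
  behavior of tau above. Treat single-dataset calls as candidates.
- The gap rule depends on histogram binning; pathological distance
  distributions (e.g. very dense near-zero neighborhoods) can merge
  genuinely distinct groups. Inspect `scan_neighbors` output when in
  doubt.
- Cross-dataset gene matching is by symbol only; probe-to-symbol mapping
  quality is the caller's responsibility.
- T is defined by the two boundary signals only, so with heavy ties at the
  boundary the anchors can collapse (T = l or T = u); such genes are
  skipped at normalization with a warning.
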