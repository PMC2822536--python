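# bimodal-expr

Detection, normalization and cross-study meta-analysis of **bimodally
expressed genes** in expression cohorts (bulk microarray or anything that
yields a gene × sample matrix of continuous, log-scale-like values).

Most genes vary unimodally around a typical level, but some — oncogene
amplicons, hormone-receptor programs, interferon modules — switch between
two distinct expression states across a patient cohort. Those *bimodal*
genes are natural binary biomarkers: each sample sits in the low or the high
mode, and small groups of co-switching genes stratify a cohort far more
robustly than individual gene signatures. This package is for
computational biologists who want to find such genes, put them on a
platform-independent ±1 scale, discover co-expressed "close neighbors"
groups, and compare calls across independent datasets.

## The method

For gene *i* with sorted signals *e*<sub>i1</sub> ≤ … ≤ *e*<sub>iM</sub>,
every split into a lower subset *L* (the *k* smallest values) and upper
subset *U* is scored by the within-subset sum of squared deviations

γ(*L*, *U*) = Σ<sub>j∈L</sub>(e<sub>ij</sub> − l)² + Σ<sub>j∈U</sub>(e<sub>ij</sub> − u)²,  l = ⟨L⟩, u = ⟨U⟩,

the 1-D two-means objective. The optimal partition minimizes γ over
*k* ∈ [1, M−1]; the threshold *T* between the modes is the midpoint of the
boundary signals. Mode separation is measured by

**τ = (u − l) / √(γ/M)**,

which is invariant under positive affine transforms of the signals (hence
comparable across array platforms). For a single normal distribution τ
tends to 2·√(2/π)/√(1−2/π) ≈ 2.647; a gene is called bimodal when τ exceeds
the conventional cutoff 2.64 *and* its standard deviation clears the 25th
percentile of the cohort's per-gene std distribution. Small isolated
subsets (< 5 % of samples) are removed as outliers before partitioning.

Bimodal genes are then rescaled by a strictly increasing piecewise-linear
map sending (l, T, u) → (−1, 0, +1); with control (normal) samples the sign
is oriented so the control mode reads +1. Groups of synchronously expressed
bimodal genes are found as the isolated near-zero cluster of cosine
distances from a query gene, and each sample is barcoded ("1-1-2-1-2") by
the signs of the group-average profiles. Across datasets, bimodal sets are
intersected on shared genes and scored with one-sided hypergeometric
(Fisher exact) tests computed in log space; genes bimodal in ≥ 3 datasets
are called *commonly bimodal*.

## Worked example

Simulate a small two-group cohort, detect, normalize, find a group and
barcode the samples:

```sh
cat > sim.yaml <<EOF
n_genes: 300
n_samples: 120
n_groups: 2
group_sizes: [4, 5]
seed: 42
n_controls: 6
EOF
bimodal simulate --config sim.yaml --out sim
bimodal detect --matrix sim/platform1.tsv --out fits.tsv
bimodal normalize --matrix sim/platform1.tsv --fits fits.tsv \
    --controls sim/platform1.controls.tsv --out norm.tsv
bimodal groups --norm norm.tsv --query G00001 --out group1.tsv
bimodal barcode --norm norm.tsv --groups group1.tsv --out barcodes.tsv
```

which prints

```
1 platform matrices written to sim
163 bimodal genes of 300 written to fits.tsv
163 genes normalized, written to norm.tsv
group of 4 genes around G00001 written to group1.tsv
126 samples barcoded with 1 groups -> barcodes.tsv
```

`fits.tsv` holds one row per gene; for the first planted bimodal gene:

```
gene    n    K   l      u      T      gamma   tau    std    n_outliers  is_bimodal  flag
G00001  126  64  4.304  6.582  5.422  18.412  5.959  1.206  0           True        ok
```

τ = 5.96 ≫ 2.64: the 64 lowest samples average l = 4.30, the rest u = 6.58,
and the threshold T = 5.42 separates the modes. (The 163/300 call count is
high because the simulated cohort is 10 % truly bimodal and the liberal
τ > 2.64 cutoff admits many null genes — the group step is what sharpens
the selection.) `group1.tsv` recovers exactly the 4 planted co-expressed
genes (cosine distances ≈ 0.24 versus ≈ 1 for unrelated genes), and
`barcodes.tsv` codes each sample `1` or `2` by the sign of the group's mean
normalized expression.

The same pipeline is available as library functions (`simulate`,
`detect_bimodal`, `normalize_dataset`, `find_close_group`,
`barcode_samples`, `pairwise_intersections`, `commonly_bimodal`, …); see
`docs/methods.md` for the full model description and design choices.

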