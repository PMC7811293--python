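# Methods

This note documents the models implemented in `cellsort`, the parameters
that matter, the synthetic data the tests rely on, and the numerical
choices made where the design was genuinely open.

## Marker table normalization

The raw table *M* (genes × cell types, entries in {−1, 0, +1}) is first
restricted to genes present in the dataset at hand ("present" = loaded
and nonzero in at least one cell; all-zero genes are removed at load).
Normalization is then two-step and sign-separated: each type's positive
entries are divided by its positive-marker count and its negative entries
by its negative-marker count; then each gene's positive entries are
divided by the number of types in which it is positive, and likewise for
negative. Divisors are marker *counts*, not weight sums, so a marker
unique to one type keeps the largest weight in its row. Counts are
recomputed **after** restriction, keeping per-type scales comparable
across datasets; a type left with no positive marker is flagged unusable
and its column zeroed. The sign pattern of *M̃* always equals that of
*M* on retained rows, and |entries| ≤ 1.

## Voting annotator

Centroids *Y<sub>mc</sub>* are means of log-normalized expression over
each cluster's cells. Z-scores are per marker across clusters with the
population standard deviation; constant rows get z = 0 everywhere.
Binarization uses *Z ≥ ζ* (ζ default 0.3; a strict `>` flag exists
because the inclusive/exclusive reading is a genuine ambiguity — at
continuous expression values the boundary case has measure zero).

The permutation null reassigns cells to clusters by a label permutation,
which preserves cluster sizes exactly; sampling with replacement is an
option flag. Each replicate recomputes *Y*, *Z*, *Z̃* and *V* in full.
Λ<sub>kc</sub> = (V<sub>kc</sub> − mean<sub>null</sub>) / sd<sub>null</sub>;
a degenerate null (sd = 0) zeroes the pair with a warning. The default
replicate count is 10⁴; the benchmark harnesses use 10³, which pilot
runs showed is ample for stable z-scores at these data sizes.

The low-support rule zeroes Λ<sub>kc</sub> when the number of supporting
markers (positive weight, binarized 1) is below 10% of the type's known
markers, counting both positive and negative markers; it applies to both
the null-z-score and the max-score variants. The max-score variant
divides *V<sub>kc</sub>* by Σ<sub>m: M<sub>km</sub>>0</sub> *M̃<sub>km</sub>* —
the score the type would reach with every positive marker supported and
no negative marker detected — so Λ ≤ 1 with equality exactly at full
support.

Labels are the per-cluster argmax; a cluster whose best score is not
positive is *Unassigned* (the z-score variant can go negative, and a
negative best score means less support than random clusters — forcing a
label there would be noise). Exact ties break to the lexicographically
first type name and are logged.

Consensus: every input score matrix is clipped at 0 and each cluster
column rescaled to maximum 1 (all-zero columns stay 0) before the
elementwise geometric mean. The clipping/rescaling bridges z-score-scaled
and frequency-scaled matrices onto a common [0, 1] scale; it is explicit
and configurable rather than implicit.

## Hopfield classifier

Attractors are the columns of *M̃* with negative entries zeroed (negative
markers carry no weight here); all-zero patterns are excluded. With p
patterns over N marker genes:

- *Q<sub>μν</sub>* = (1/N) Σ<sub>i</sub> ξ̃<sub>i</sub><sup>μ</sup> ξ̃<sub>i</sub><sup>ν</sup>,
  inverted exactly, or by pseudo-inverse (relative cutoff 10⁻¹⁰, with a
  warning) when patterns are linearly dependent;
- *J<sub>ij</sub>* = (*A<sub>ij</sub>*/N) Σ<sub>μν</sub> ξ̃<sub>i</sub><sup>μ</sup> (Q⁻¹)<sub>μν</sub> ξ̃<sub>j</sub><sup>ν</sup>,
  with *A* the user network's adjacency restricted to the marker genes
  (genes absent from the network get zero rows) or the complete
  zero-diagonal graph when no network is given.

Spins start at σ<sub>i</sub> = +1 where the cluster's centroid z-score is
≥ ζ, else −1 (no zeros at initialization). Each step selects every node
independently with probability ramping linearly from 0.025 to 0.5 over
the first 100 steps, then constant; selected nodes draw +1 with
probability (1 + e^(−2h/T))⁻¹ on the field h = Jσ + h_ext, computed from
the state at the start of the step. The modified transition table: +1
drawing −1 parks at 0; 0 drawing +1 recovers to +1; 0 drawing −1 stays 0;
−1 behaves classically. This asymmetric dilution prevents stochastic
down-flips of correctly-on genes from being amplified. At T ≤ 0 the
deterministic limit sign(h) applies, with a fair coin at h = 0.

Unstated parameters fixed here: temperature T = 0.2 (small enough that
stored patterns are stable in pilot runs while leaving the dynamics
stochastic), 200 total steps (the schedule only defines the first 100),
10 repetitions per cluster, h_ext = 0. All are configurable, and the
benchmark results are insensitive to the exact values.

Overlaps m<sup>μ</sup> = (1/N) Σ<sub>i,ν</sub> σ<sub>i</sub> ξ̃<sub>i</sub><sup>ν</sup> (Q⁻¹)<sub>νμ</sub>
are normalized so that σ = ξ̃<sup>μ</sup> gives exactly m<sup>μ</sup> = 1
(a row of QQ⁻¹). For classical ±1 memories m ∈ [−1, +1]; for the sparse
non-negative marker attractors a binarized state can mathematically
exceed 1 — classification only uses the argmax over non-negative
overlaps, so this does not affect labels. Each repetition's label is the
argmax attractor (or *Unassigned* if every final overlap is negative);
the modal label over repetitions wins, with label frequencies forming the
cluster's score column (frequencies sum to 1 including *Unassigned*).

## Quasi-energy landscape

E(σ) = −½ σᵀJσ. The landscape default builds J **with** the adjacency
and **without** the Q correction (plain Hebbian storage); both toggles
are exposed. Basins are sampled by binarizing each attractor
(entry > 0 → +1, else −1 — the natural spin encoding of "marker on") and
flipping signs independently at rates {0.05, 0.1, 0.2, 0.3}, 1000 draws
per attractor and rate by default. The 2D projection axes are the first
two principal components of the attractor states alone, so attractor
coordinates are independent of the number of noise samples. For a single
±1 pattern on the complete zero-diagonal graph, E(pattern) = −(N−1)/2
exactly (to machine precision in floating point).

## Isolation forest

Written from first principles. Trees grow on uniform without-replacement
subsamples of ψ = 256 cells; each node picks a uniformly random gene
among genes non-constant in its cells and a threshold uniform on that
gene's (min, max); recursion stops at single cells or unsplittable
duplicates. There is **no height limit** — the expected-depth correction
c(s) = 2H(s−1) − 2(s−1)/s (H(i) = ln i + γ; c(1) = 0, c(2) = 1 exactly)
applies only at multi-cell duplicate leaves, and is the same c used for
the score normalization c(ψ) ≈ 10.244 at ψ = 256. Scores are
s = −Σh/(c(ψ)n): a negative number whose magnitude is the average path
length in units of c(ψ); larger (closer to 0) = more anomalous. Ranking
by s is a monotone transform of the canonical score 2^(−E(h)/c(ψ))
(verified by a rank-correlation test). Scoring runs on the same
median-depth log-normalized matrix as annotation; a PCA-reduced option
exists but is off by default. Tied scores break by cell order and are
logged.

## Quality control and normalization

Count depth, detected-gene count and mitochondrial fraction are computed
per cell; depth/gene thresholds are 50% of the cohort medians (midpoint-
interpolated). The mito cutoff is the x-intercept of the straight line
through two points of the mito-fraction density — at the median and at
median + 1.5 population SD — where the density is a Gaussian KDE with
Scott's-rule bandwidth. This is a smooth-density reading of an
"abscissa interception" construction that could equally be done on a
histogram; the KDE makes the cutoff deterministic and binning-free. If
the line does not descend or the fractions are constant the rule is
disabled with a warning. Normalization scales each cell to the median
pre-scaling depth and applies natural log(1 + x); the scale target and
log base are configurable.

## Synthetic data

The generators emulate the benchmark designs at desk scale. Counts are
negative binomial with per-gene base means drawn log-normal (log-mean 0,
log-sd 1 — median 1 count/cell) and fixed dispersion r = 2
(var = μ + μ²/r), an overdispersion typical of droplet counts. A cell of
planted type k has its positive markers' means multiplied by (1 + effect)
and its negative markers' divided by it; effect = 5 (6-fold contrast) is
the default planted signal. Mixtures draw 8 types in Dirichlet-random
fractions with a 40-cell floor per type so every cluster is usable,
~2000 cells per mixture, 20 mixtures — sizes chosen to exercise the full
pipeline while keeping a laptop-scale runtime.

Anomaly spike-ins model a foreign cell type: 30% of genes (chosen
uniformly) get their base mean multiplied by (1 + shift), another 30%
divided by it, and the profile is rescaled to the base total so
sequencing depth matches the background — mirroring the benchmark's
depth-matched datasets, and necessary because otherwise depth alone gives
the spike-ins away. shift = 9 (10-fold) was calibrated once by pilot
runs as the distance at which detection is reliable but not saturated;
a uniform log-normal multiplier profile and an expressed-genes-only
variant were piloted and rejected (the former has heavy realization-to-
realization luck, the latter hides spikes inside the background's
marginal ranges). The `same` mode draws spike-ins from the background
profile itself, the negative control.

What the generators do **not** emulate: dropout structure beyond NB
zeros, batch effects, gene–gene correlation, or the label granularity
problems of real marker lists. Passing benchmarks here shows the
algorithms recover planted structure under realistic count noise, not
that they resolve closely related subtypes in real tissue.

## Degenerate inputs and tie-breaks

Duplicate gene or cell identifiers are errors, never merged. Constant
marker rows binarize to all-zero. Empty clusters are errors. Zero-depth
cells fail normalization with a pointer to QC. Score ties break
lexicographically (types) or by input order (cells), always logged.
Every stochastic stage takes one seed; multi-part stages derive child
seeds (kept below 2³¹) from it by counter, so stages are independently
reproducible and fixed-seed runs are bit-identical.

## Known limitations

- Gene matching is exact string equality (an optional two-column synonym
  file can be applied); no identifier-convention conversion.
- The Hopfield node set is the restricted marker genes only; network
  edges outside it are ignored.
- The mito cutoff is a density-construction choice, not a fit to any
  particular published figure.
- Batch correction, t-SNE/UMAP, graph clustering and figure rendering
  are out of scope; clustering is a replaceable convenience
  (external labels can be supplied everywhere).
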