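# cellsort

Knowledge-based cell-type annotation for clustered single-cell RNA-seq
data, for bioinformaticians who have a count matrix and a marker/cell-type
table and want automatic, statistically qualified cluster labels — plus
isolation-forest anomaly scoring, quality control, and Hopfield
quasi-energy landscape export.

## What it computes

**Marker voting with a permutation null.** Prior knowledge is a matrix
*M<sub>km</sub>* ∈ {−1, 0, +1}: gene *m* is a positive (+1) or negative
(−1) marker of cell type *k*. After restricting to genes present in the
dataset, *M* is normalized separately for positive and negative markers —
first by each type's marker count, then by the number of types using each
marker — so type-specific markers carry large weights (*M̃*). For each
cluster *c* the centroid *Y<sub>mc</sub>* (mean log-normalized expression)
is converted to per-marker z-scores across clusters and binarized at
ζ = 0.3 into *Z̃<sub>mc</sub>*. The voting score

&nbsp;&nbsp;&nbsp;&nbsp;*V<sub>kc</sub>* = Σ<sub>m</sub> *M̃<sub>km</sub> Z̃<sub>mc</sub>*

is referred to a null distribution obtained by reassigning cells to
clusters at random (sizes preserved, 10⁴ replicates by default);
Λ<sub>kc</sub> is the z-score of *V<sub>kc</sub>* in that null, zeroed
when fewer than 10% of a type's known markers support the pair, and each
cluster gets *T<sub>c</sub>* = argmax<sub>k</sub> Λ<sub>kc</sub> (or
*Unassigned* when nothing scores positive). A second variant divides
*V<sub>kc</sub>* by the best score the type could reach, giving Λ ≤ 1.

**Hopfield attractor classification.** The non-negative columns of *M̃*
are stored as attractor patterns ξ̃ of a Hopfield network on the marker
genes, with projection-rule couplings
*J* = (*A*/N) ξ̃ᵀ *Q*⁻¹ ξ̃ restricted to a gene–gene interaction network
*A* (complete graph by default). Each cluster's binarized centroid
z-scores initialize spins σ ∈ {−1, +1} which evolve by stochastic
asynchronous dynamics with a +1→−1 transition parked at 0; the attractor
with the largest non-negative correlation-corrected overlap at the final
step labels the run, and repeated runs vote. The voting and Hopfield
score matrices combine into a consensus by a per-cluster rescaled
geometric mean.

**Anomaly scoring.** An isolation forest (100 trees, subsample ψ = 256)
built from scratch: random gene, random split, grown to full isolation.
A cell's score is *s* = −Σ<sub>j</sub> *h<sub>ij</sub>* / (*c*(ψ)·*n*)
over its per-tree path lengths; scores closer to 0 mean easier isolation,
i.e. more anomalous.

**Quality control.** Cells below 50% of the median count depth or
detected-gene count are flagged, plus a mitochondrial-fraction cutoff
taken where the line through the mito-fraction density at the median and
at median + 1.5 SD crosses zero density.

**Landscapes.** The quasi-energy *E* = −½ σᵀ*J*σ is sampled around each
attractor by sign-flip noise and projected on the attractors' first two
principal components, exported as an (x, y, E) table.

## Worked example

Everything is testable without downloads — the `cellsort.synthetic`
module generates marker tables, planted-type mixtures, spike-in
anomalies and random gene networks. From `examples/annotate_mixture.py`
(an 8-type, ~2000-cell mixture in random fractions):

```
voting     weighted F1 = 1.000   unassigned = 0.0%
hopfield   weighted F1 = 1.000   unassigned = 0.0%
consensus  weighted F1 = 1.000   unassigned = 0.0%
```

Each line is one annotator's support-weighted F1 against the planted
truth over assigned cells; 1.000 means every cluster received its planted
type. From `examples/anomaly_scoring.py` (20 foreign-phenotype cells
spiked into 1600 typical cells):

```
rank-threshold AUC: 0.996   (1.0 = spike-ins perfectly separated, 0.5 = chance)
spike-ins among the top-20 ranked cells: 18/20
```

The other examples cover QC/normalization and the landscape export. The
same stages are scriptable through the `cellsort` CLI
(`cellsort qc|cluster|annotate|anomaly|landscape|synth|eval|run`), with
one root seed making every run bit-reproducible.

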