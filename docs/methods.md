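# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `spotcna`, and what the simulated validation does and
does not establish.

## Expression model of copy number

The working assumption is the standard one for expression-based CNA
inference: a chromosomal gain or loss shifts the transcriptional output of
many contiguous genes by a common factor, while biological regulation of
individual genes is locally incoherent. Smoothing reference-centred
log-expression along the genome therefore integrates the coherent copy
number signal and averages out per-gene regulation. The approach inherits
the usual caveats: strongly co-regulated gene neighborhoods (e.g. immune
loci) can mimic CNAs, focal events smaller than the smoothing window are
invisible, and everything is relative to the reference population — a
genome-wide ploidy shift shared by all malignant cells is not observable.

### Normalization and capping

Counts are normalized per bead to counts-per-million before log transform.
UMI counts carry no gene-length bias, so no length correction is applied
even though the transform is conventionally called TPM. The symmetric cap
at ±3 (log₂ scale, after reference centring) bounds the influence of any
single gene; at Slide-seq sparsity most nonzero genes sit at the cap, so
the smoothed signal is effectively a locally weighted detection rate
relative to the reference — this is what makes the method workable at a few
hundred UMIs per bead.

### Order of preprocessing operations

Gene filter (total ≤ 300 dropped) precedes the bead filter so bead totals
reflect retained genes; beads with zero counts are always removed (TPM is
undefined for them); the low-UMI trim removes the poorest beads first, ties
broken by bead id, stopping as soon as sub-100-UMI beads are ≤ 35 % of the
survivors. chrM and chrY genes are removed after centring and capping, and
the gene set is intersected with the gene-position table since unplaced
genes cannot be smoothed.

### The two post-smoothing centrings

After smoothing, each bead is centred on its own mean smoothed intensity,
and then each gene is centred on its mean over reference beads. The
per-bead step is load-bearing: the expected log(TPM+1) profile of a sparse
bead depends on its depth (a deep bead spreads detections over more genes),
so without a per-bead baseline any depth difference between the reference
and malignant populations appears as a global copy number offset. With it,
only the relative structure along the genome survives. Inverting the log
then puts copy-neutral at 1.

## Binning

The pseudo-distance weights (k_spatial = 55, k_expression = 1) deliberately
make physical proximity dominate: bins are compact spatial patches of ~12
beads whose pooled counts (~10× a single bead) carry usable CNA signal,
with the expression term only discouraging the merger of transcriptionally
discordant neighbors. Distances use raw micrometres and raw intensity units
with no standardization. Ward linkage is run directly on the pseudo-distance
(the ward.D2 criterion on a precomputed dissimilarity; verified to match R's
`hclust(..., "ward.D2")` cut-for-cut). Bin count per population is
round(n/12), round-half-to-even, minimum 1; malignant and non-malignant
beads are binned separately and never share a bin.

Bin CNA scores are the unweighted bead means clamped to [0.6, 1.4]. A
UMI-based shrinkage of low-depth bins toward copy-neutral
(`umi_scaling="shrink"`, deviation × min(1, umi/median umi)) is available
but **off by default**: the per-bead baseline centring already removes
depth artifacts, and on simulated data the shrinkage measurably distorts
CNA amplitude wherever depth correlates with position, degrading clone
assignment. The no-op default keeps the score an honest local average.

## Clone calling

k_malignant is selected on malignant bins only (Ward on Euclidean distances
between CNA score rows; mean silhouette width over k = 2…min(10, n−1); ties
to the smaller k; silhouette uses the same Euclidean metric and matches the
R `cluster::silhouette` convention, including s(i) = 0 for singletons). All
bins are then re-clustered jointly and cut at k_malignant + 1; the cluster
with the highest non-malignant-bin fraction is designated normal. On data
where clone profiles form a continuum (e.g. gradual spatial admixture) the
position of the Ward cut along that continuum is the dominant source of
assignment variance — see the validation section.

## Differential expression

DGE runs on raw bead counts grouped by their bin's cluster, preserving
count distributions for the negative binomial model. Per gene and cluster:
NB GLM with log link, an intercept, a cluster indicator, and a log
total-UMI offset. The NB2 dispersion α (variance μ + αμ²) is estimated by
the Cameron–Trivedi moment estimator from a Poisson fit, falling back to
the Poisson family when α ≤ 0; significance is the Wald p-value of the
indicator, Bonferroni-corrected over all genes × clusters tested. Measured
calibration at n = 200 beads/group, dispersion 0.5: null type-I error
within the binomial 95 % interval of the nominal 0.05, power > 0.99 for
4-fold effects. The reported log₂ fold change is the pseudocounted ratio of
mean normalized expression (finite even when one group is all zeros; such
genes are flagged).

## The simulator

The generator reproduces the study design used to validate the original
approach: a 3000 × 3000 µm field; 6000 non-malignant and 7000 cells per
malignant clone; the non-malignant population either a separate 300 µm band
at the top of the field ("separated") or intermixed ("mixed"); two malignant
clones forming opposing linear gradients over 100 zones of 30 µm with
ratios 99:0 … 0:99; 10,000 beads (2000 at desk scale) at random integer
coordinates; bead expression as a Gaussian-kernel-weighted sum of nearby
cell profiles with σ = 1500·√(1/N_cells) µm, truncated at 3σ, stochastically
rounded (floor + Bernoulli, preserving expectation); binomial thinning for
capture efficiency. Beads are annotated by majority constituent (reference
when the normal population is the largest kernel-weight contributor),
mirroring majority-cell-type annotation of real beads.

Cell profiles are synthetic: 1000 genes on 10 chromosomes with equal p/q
arms; per-gene lognormal(0, 1) baseline means scaled so a copy-neutral cell
expects 5000 total counts — at 10 % thinning this yields a median of ~600
UMI/bead, in the range reported for real pucks; negative binomial sampling
with dispersion 0.5; clone CNAs as per-arm fold changes (default: four
disjoint altered arms per clone, gains 1.5×, losses 0.5×, balanced so total
output is depth-neutral). Not modelled: barcode errors, spatial capture
bias, cell-type expression programs beyond CNA (so reference contamination
by misannotation is milder than in real data), and segmentation artifacts.
Passing the simulated suite therefore demonstrates correct recovery of
arm-scale clonal structure from sparse, spatially mixed readouts — not
robustness to annotation error or platform artifacts.

## Validation behavior and known limitations

With the desk-scale study (2000 beads, 1000 genes, seed 1) the pipeline
selects k_malignant = 2, recovers the direction of all 8 implanted arm
alterations, and correlates with the implanted arm profile at Spearman
ρ ≈ 0.89 — per clone, the maximum attainable given ties among the four
altered arms — in every scenario and at 25 %, 10 % and 2 % thinning.
Bin-level clone assignment accuracy is threshold-grade but noisier: across
10 simulation seeds it averages 0.91 ± 0.03 (separated, 10 %), with the
mixed scenario lower on average (0.81). Two effects bound it: bins
straddling the gradient midline are genuine ~50:50 clone mixtures whose
ground-truth label is itself a coin flip (a ceiling of ~0.92 even for an
ideal classifier), and the greedy Ward cut has no natural boundary on a
profile continuum, so its position wobbles seed to seed. Both are
properties of the gradient study design rather than of the inference code;
on data with discrete clone territories the cut is stable.

Arm-level Spearman comparisons exclude arms without CNA signal
(|mean score − 1| < 0.02, configurable) in either profile; rank correlation
over profiles that are mostly exact ties is not meaningful, and with only
4 of 20 arms altered the all-arm statistic is bounded at 0.70 regardless of
inference quality. Pairs sharing fewer than 3 signal arms are reported as
undefined rather than fabricated.

## Reproducibility

All inference stages are deterministic; randomness exists only in the
simulator and is governed by a single seed. Pipeline runs write a manifest
(package version, full configuration, seed) beside their outputs, and
repeated runs with the same configuration produce byte-identical tables.
Plots are side effects; every downstream consumer reads tables.
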