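# Methods

`glioniche` re-implements, as a reusable and tested pipeline, the analysis
chain used in spatial-transcriptomic studies of malignant glioma niches:
estimating per-spot tumor content from expression-inferred copy number,
discovering recurrent niche expression programs ("meta-modules") by
correlating per-sample cluster signatures, assigning each spot a niche,
relating CNV subclones to niches, quantifying isoform switching between
niches, decomposing spots into cell types, and classifying expression trends
along invasion trajectories. Because the patient datasets such analyses run
on are access-restricted, the package ships a synthetic Visium-like generator
with full planted ground truth, and every claim its tests make is a recovery
statement about that generator.

## Synthetic data generator

One simulated sample is a hexagonal offset-row lattice (default 32x32, 1,024
spots; pixel coordinates are an affine map of array coordinates, giving each
spot six equidistant neighbors). Each spot is a mixture of seven cell types
(malignant, astrocyte, oligodendrocyte, OPC, neuron, endothelial, immune).
The default "concentric" layout mirrors glioma histology: a small hypoxic
center, a tumor-core ring, an invasive annulus, a normal rim, and a few
contiguous vascular blobs. Per-niche microenvironment compositions make the
invasive niche neuron-rich and the vascular/hypoxic niches
endothelial/immune-rich.

Counts are drawn gene-wise from a negative binomial (dispersion 0.5, i.e.
variance mu + 0.5 mu^2) around the mixture mean, scaled to a log-normal
library size (median 10,000 UMIs, sigma 0.35). On top of the cell-type
mixture:

- **Niche programs.** 60 module genes per tumor niche are upregulated
  (fold 2 by default) in spots of that niche.
- **Subclonal CNVs.** Each subclone carries whole-chromosome events; a gene
  in an event region has its mean multiplied by `1 + f (m - 1)` where `f` is
  the spot's tumor fraction and `m` the event multiplier — spots are
  mixtures, so the CNV signal is diluted by non-malignant content. The
  default configuration has a truncal clone (chr1 gain x1.5, chr7 gain x1.5,
  chr10 loss x0.5) everywhere and a derived clone adding a chr5 loss in an
  angular sector.
- **Tumor fraction.** The default field assigns per-niche plateau levels
  (hypoxic 0.90, core 0.85, vascular 0.50, invasive 0.45, normal exactly 0)
  plus a smooth spatial jitter (sd 0.08). Plateaus rather than a radial ramp
  keep within-niche expression homogeneous — the niches of interest are
  discrete histological domains — while the jitter keeps tumor content
  continuously variable so rank-based recovery is meaningful. A "plateau"
  field (0.95 in all tumor niches) and a "zero" field (no tumor) are
  available for focused scenarios.
- **Spot swapping.** Each UMI independently stays in its spot with
  probability `1 - bleed_rate` (default 0.25) or moves to another spot with
  Gaussian-distance weights (sd 1.5 spot spacings); totals are conserved
  exactly, and bleeding UMIs keep their gene identity.
- **Isoform switches.** 40 switch genes (drawn with elevated base expression
  so that per-spot read depth supports PSI) each have two isoforms; the gene
  count is split binomially with isoform-A proportion 0.8 in one niche, 0.2
  in a second, 0.5 elsewhere. Six planted splicing-factor genes are
  upregulated (x3) in the high niche of each niche pair, so their expression
  co-varies with PSI. Setting `isoform_switching=False` yields null data with
  constant 0.5 mixing.
- **Variant reads.** Coverage of a mutant locus is Poisson with mean
  `rate x spot UMI total` (default rate 1e-5, matching the ~1-in-100,000
  sparsity of 3'-capture reads over a mid-transcript locus); mutant reads are
  binomial in the spot's tumor fraction, hence absent from normal spots.

What the generator does **not** emulate: read-level artifacts (sequencing
error, mapping), segmental (sub-chromosomal) CNVs, continuous cell-state
gradients within a niche, batch effects between samples (samples differ only
through sampling noise and layout jitter), and dropout beyond what the
negative binomial induces. Passing tests therefore demonstrate correctness
of the algorithms and recoverability under idealized but realistically sized
and contaminated data — not performance on patient tissue.

## QC, normalization, clustering, signatures

Spots failing `detected genes >= 200` or `mitochondrial fraction <= 25%`
(strict inequalities on the failing side) are removed; expression is
`log(1 + 1e4 * count / spot_total)`.

Spatially informed clustering augments each spot's expression principal
components with the principal components of its spatial-neighbor mean
expression, weighted `sqrt(1-lambda)` and `sqrt(lambda)` (default
lambda = 0.2, 6 neighbors = the first hex ring, 20 PCs), and runs Leiden on
a 15-NN graph of the augmented features. `lambda = 0` reduces to purely
transcriptional clustering. The default resolution is 0.3: on the default
generator output this yields one cluster per planted niche, whereas higher
resolutions split homogeneous niches into sibling clusters — and because
marker genes shared between clusters are excluded (see below), sibling
clusters of one niche would strip each other of exactly the genes that
define the niche. Resolution, lambda and k remain configurable.

Cluster signatures use one-vs-rest Wilcoxon rank-sum tests with
Benjamini-Hochberg adjustment; a gene is significant if log2FC > 0.25 and
adjusted p < 0.05, with log2FC computed Seurat-style as
`log2((mean expm1(in)+eps)/(mean expm1(out)+eps))`, eps = 1e-9. Clusters
with fewer than 50 significant genes are dropped; genes significant in more
than one cluster are excluded from all; the top 50 by log2FC are kept (ties
broken by smaller adjusted p, then gene id, for determinism).

## CNV scoring and tumor content

Per spot, log-normalized expression minus the mean over reference (normal)
spots is smoothed by a centered moving average of 100 genes within each
chromosome (truncated at chromosome boundaries; windows shrink with a warning
on short chromosomes), median-centered per spot, and mapped into [0.7, 1.3]
by `score = 1 + 0.3 clip(smoothed / s, -1, 1)` with saturation `s = 0.3`.
The fixed saturation (rather than a data-driven min/max rescale) anchors
1.0 at the reference mean, keeps null data near 1.0 instead of inflating
noise to fill the range, and places a clonal ~1.4-fold sustained deviation at
the scale edge; 0.3 was chosen because log1p pseudocount compression at
typical per-gene depths (a few counts) attenuates a 2-fold clonal loss to
roughly 0.3-0.45 on the smoothed log scale, which then lands safely past the
0.8 event threshold.

Signature events are maximal contiguous regions whose mean score over
candidate tumor spots exceeds 1.2 (gain) or falls below 0.8 (loss), at least
10 windows long. Candidate spots default to the top decile by total absolute
deviation — an automatic surrogate for the histology used in practice. Tumor
content per event is `C = (A-1)/(max A - 1)` for gains and
`C = (1-A)/(1 - min A)` for losses (A = spot mean score over the event
region; max/min over the sample's QC-passing spots), clipped to [0, 1];
spots with consensus `C > 0.2` (strict) are malignant. The consensus over
events is the per-spot median; at least three events are expected and fewer
triggers a warning.

## Meta-modules and niches

Signatures are scored per spot with a control-bin score: genes are binned
(24 bins) by data-wide mean expression, 100 control genes are drawn per set
gene from the matching bin (seeded), and the score is mean(set) −
mean(controls). Signatures are scored within each sample and concatenated
rather than on a cross-sample embedding, avoiding a batch-integration step
the synthetic data does not need.

Three integration strategies produce a signature-signature correlation
matrix: (1) Pearson over spots; (2) Pearson over per-cluster pseudobulk
means; (3) spatially weighted correlation — at every spot a local Pearson
matrix under Gaussian kernel weights with adaptive bandwidth (distance to
the ceil(0.1 n)-th neighbor), averaged over spots, then over samples. As the
bandwidth grows the local correlation converges to the global Pearson
correlation, which the tests verify to 1e-6 using a fixed-bandwidth
override. Each matrix is clustered with average linkage on distance
1 − r and cut at k = 4 modules; partitions are compared by pair-counting
Jaccard. Niche assignment z-normalizes each module's score across spots and
labels every spot by argmax, ties going to the first module in canonical
order (logged).

## Subclones

Malignant spots are clustered by average-linkage hierarchical clustering on
their CNV score vectors (Euclidean, on the fixed [0.7, 1.3] scale, no
standardization). The dendrogram is descended until every cluster is pure in
its per-spot event-presence pattern (event-region mean crossing 1.2 / 0.8),
and branches with identical patterns are merged; subclones are ordered by
ascending event count (the most parsimonious interpretation: ancestral
clones carry fewer events). A subclone is niche dominant when strictly more
than 75% of its spots share one niche label. Subclone-focused test scenarios
plant pronounced events (gains x2.0, losses x0.3) with contamination off, so
that per-spot event presence is unambiguous and the partition/dominance
logic — not the CNV detection limit, which the tumor-content checks exercise
at x1.5/x0.5 — is what is tested.

## Isoforms

Isoform tables are filtered isoform-first (expressed in >= 50 spots), then
spot-wise (>= 100 detected isoforms), both strict-< removal rules. PSI for
an ordered pair is exactly IR/(IR+ER) on raw counts, defined only where
IR+ER >= 5. Differential isoforms use pairwise niche Wilcoxon tests on
log-normalized isoform expression with thresholds p < 0.01, |log2FC| > 0.1
and expressing-fraction > 0.1 (niches with fewer than 3 spots are skipped).
A DEI is conserved when the same (isoform, enriched niche) recurs in >= 2
samples (configurable; "across samples" is interpreted as at-least-two), and
a gene is a switch gene when two of its isoforms are conserved DEIs whose
enriched-niche sets are not confined to one common niche. Splicing-factor
association requires the factor itself to be differential across the gene's
niche pair and Spearman |rho| >= 0.3 against PSI over spots with defined PSI
(>= 20 required); rho > 0 marks consistency with the IR isoform.

## Deconvolution and ligand-receptor pairing

Spot deconvolution is non-negative least squares of linear-scale
depth-normalized expression onto per-type mean reference profiles
(references built from provided profiles or by averaging up to 500 sampled
cells per type, seeded), with coefficients normalized to fractions. This is
a deliberate simplification of platform-aware mixture models; the niche
aggregation downstream — mean cell-type fraction per niche — is preserved
exactly. Duplicate reference profiles abort with the colliding type names.
Ligand-receptor hits are pool pairs whose two partners belong to the same
module's gene set; tumor/normal homonym types ("AC-like" + "AC") can be
merged by summing fractions.

## Trajectories

Spots within half the corridor width (default 90 pixel units, interpreted as
full width) of a user-drawn polyline are ordered by projected arc length
(ties by perpendicular distance). Gene expression is averaged in 20 equal
arc-length bins (empty bins merge into neighbors, logged), min-max
normalized, and correlated against unit-maximum Gaussian templates centered
at 0.15 / 0.50 / 0.85 with sigma 0.15; a gene takes the best template's
label if r >= 0.5, else "none". Binning by clipped floor of normalized
position makes polyline reversal map bin i to bin n-1-i exactly, so reversal
swaps early and late labels with identical correlations.

## Problem sizes and determinism

The default test and acceptance conditions are 3 samples x 1,024 spots x
2,000 genes across 10 chromosomes, 40 switch genes, and 100 replicate null
datasets (2 samples, 196 spots, 400 genes each) for the false-switch check —
sizes at which every planted structure is comfortably recoverable and a full
run takes well under a minute on one CPU. All stochastic steps (generator,
Leiden, control-gene sampling, reference subsampling) take explicit seeds;
the pipeline derives per-stage child seeds from one global seed by hashing,
so stages can be re-run in isolation, and the run manifest records seeds,
parameters and SHA-256 hashes of every output.

## Known limitations

- Event designation near threshold: clonal 1.5x gains at tumor fraction
  ~0.9 sit close to the 1.2 line after pseudocount compression, so the set
  of designated events can vary between samples; the median consensus over
  >= 3 events absorbs this for tumor content, but subclone event patterns
  built from borderline gains can fragment.
- When a niche is split into two clusters, the shared-marker exclusion rule
  removes the niche-defining genes from both signatures; the residual
  signatures usually still co-cluster with their niche, but their module
  membership is less stable.
- NNLS deconvolution ignores platform effects and count noise models; with
  mismatched or collinear (non-duplicate) references its errors grow
  gracelessly.
- The spatially weighted correlation averages local matrices uniformly over
  spots; no small-sample correction is applied to local correlations at
  sparse lattice edges.
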