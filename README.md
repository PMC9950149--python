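# glioniche

Niche decomposition of spatial glioma transcriptomes: CNV-based tumor
content, meta-module discovery, subclone niche dominance, isoform switching,
spot deconvolution, and invasion trajectories — with a synthetic Visium-like
data generator carrying full planted ground truth.

## Who this is for

Malignant gliomas organize into spatially segregated niches — tumor core,
vascular, invasive, and hypoxic regions — each with its own transcriptional
program, cell-type ecosystem, and RNA-isoform usage. Analyses of 10X
Visium-style data that resolve this structure are usually stitched together
from many tools and one-off scripts. `glioniche` packages that chain as a
tested Python library for method development and benchmarking: every stage
is a plain function over pandas/numpy containers, and a built-in simulator
plants niches, subclonal copy-number events, cell-type mixtures, spot-to-spot
contamination, and isoform switches so that each stage's output can be scored
against known truth.

## The core quantities

- **Tumor content.** Per spot, log expression relative to a normal reference
  is smoothed by a moving average of 100 genes along each chromosome and
  rescaled to CNV scores in [0.7, 1.3]. Contiguous regions with candidate
  mean score > 1.2 (gain) or < 0.8 (loss) are *tumor signature CNV events*;
  with A_CNVi the spot's mean score over an event region,

      C_i = (A_CNVi − 1) / (max A_CNV − 1)   (gain)
      C_i = (1 − A_CNVi) / (1 − min A_CNV)   (loss)

  and a spot is malignant when the median C over ≥ 3 events exceeds 0.2.
- **Meta-modules.** Per-sample spatially informed clusters (Leiden on
  neighborhood-augmented expression PCs) yield ≤ 50-gene marker signatures;
  signatures are integrated into k = 4 modules by hierarchical clustering of
  their correlation — over spots, over pseudobulks, or spatially weighted
  (Gaussian-kernel local correlations averaged over locations) — and
  partitions are compared by pair-counting Jaccard. Each spot's niche is the
  argmax of its z-normalized module scores.
- **Subclone dominance.** Malignant spots are split into CNV subclones by
  average-linkage clustering cut at event-pattern purity; a subclone is
  niche dominant if > 75% of its spots share a niche.
- **PSI.** For an isoform pair, PSI = IR/(IR+ER) per spot with ≥ 5 reads;
  differential isoforms (p < 0.01, |log2FC| > 0.1, pct > 0.1, pairwise
  Wilcoxon between niches) conserved across samples define isoform-switch
  genes.

See `docs/methods.md` for the full model and parameter account.

## Worked example

```python
from glioniche.simulate import SimConfig, generate_dataset
from glioniche import preprocess as pre, cnv

ds = generate_dataset(SimConfig(seed=7))          # 3 samples, ~1,000 spots each
sample, truth = ds.samples[0], ds.truths[0]

qc = pre.qc_filter(sample)                         # genes >= 200, mito <= 25%
expr = pre.lognormalize(sample.counts)

reference = list(truth.spots.index[truth.spots["niche"] == "normal"])
profile = cnv.infer_cnv(expr, sample.genes, reference)   # moving average of 100 genes
events = cnv.designate_signature_events(profile)
for e in events:
    print(f"event: {e.chrom} {e.direction} ({e.n_windows} windows, "
          f"candidate mean {e.candidate_mean:.2f})")
consensus, concordance = cnv.robust_content(profile, events)
print("malignant spots (C > 0.2):", int((consensus > 0.2).sum()))
```

prints

```
event: chr1 gain (146 windows, candidate mean 1.25)
event: chr7 gain (200 windows, candidate mean 1.26)
event: chr10 loss (200 windows, candidate mean 0.72)
malignant spots (C > 0.2): 454
```

The generator planted a truncal clone with chr1/chr7 gains and a chr10 loss;
all three are designated as signature events spanning their chromosomes, and
the 454 spots called malignant are those whose planted tumor fraction is
appreciable (the consensus C ranks spots by planted tumor fraction with
Spearman ρ ≈ 0.9 on this dataset). Downstream, `glioniche.modules`
integrates the cluster signatures into the four niche programs,
`glioniche.subclones` quantifies niche dominance, `glioniche.isoforms`
recovers the planted switch genes, and `glioniche.microenv` recovers the
planted cell-type fractions.

A command-line interface mirrors the stages:

```bash
glioniche simulate --seed 7 --out data/
glioniche cluster --sample data/sample1 --out clusters.tsv
glioniche run --seed 7 --out results/    # full pipeline + manifest
```

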