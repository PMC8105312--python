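# bgcpipe

Desk-scale tooling for studying how biosynthetic gene clusters (BGCs) sit in
plant genomes and how they evolve. Plant BGCs — physically co-located,
non-homologous genes that jointly encode a metabolic pathway, like the
12-gene avenacin cluster in diploid oat — raise a set of recurring
quantitative questions, and `bgcpipe` implements the statistics behind them
as a tested Python library:

* **Where do clusters pile up?** A sliding-window *cluster density score*,
  `score = n_clusters / n_genes` per window (default 100 Mb window, 10 Mb
  slide), normalises cluster counts by gene density and ranks hotspot
  windows deterministically.
* **Is a candidate cluster co-expressed?** DESeq2-style median-of-ratios
  size factors, Pearson correlation of member genes against a bait gene,
  and the filter "at least 3 member genes with r > 0.85", plus per-gene
  Z-score matrices for heatmaps.
* **How big is the genome?** From a k-mer occurrence spectrum,
  `Gs = (Kn − Ku)/Dp` (total minus singleton k-mer instances over the
  coverage-peak depth), and from flow cytometry, 2C pg via the G1-peak
  ratio against an internal standard and 1 pg = 0.978 × 10⁹ bp.
* **How fast are cluster genes evolving?** Pairwise dN/dS by NG86 counting
  (with Jukes–Cantor correction) and by maximum likelihood under the
  Goldman–Yang (GY94) codon model over the 61 sense codons, with the
  likelihood-ratio test of ω = 1 against χ²(1); divergence dating by
  T = Ks/(2r) with a default grass clock of r = 6.5 × 10⁻⁹ /site/year.
* **Does gene order follow pathway order?** A Kendall tau-b colinearity
  statistic between telomere distance and biosynthetic step rank, with a
  permutation p-value.
* **Synthetic data for all of it.** Generators for planted-hotspot
  annotations, tissue-structured negative-binomial count matrices with a
  planted co-expressed module, k-mer spectra with error and repeat
  components, and codon pairs evolved under GY94 with known t, κ, ω — so
  every stage is testable end-to-end with known ground truth.

## Worked example

```python
from bgcpipe import (AnnotationSimConfig, gen_annotation, window_scan,
                     rank_hotspots, estimate_genome_size_from_totals)

# genome size from published spectrum totals
est = estimate_genome_size_from_totals(kn=124_199_810_495,
                                       ku=12_260_521_110, dp=29)
print(est.format_gb())                # -> 3.86 Gb

# planted-hotspot recovery on a 10 Mb toy chromosome
cfg = AnnotationSimConfig(chromosome_lengths=(10_000_000,), n_genes=(1000,),
                          background_cluster_rate=0.002,
                          hotspot=(0, (4_000_000, 5_000_000), 0.05), seed=7)
genes, clusters = gen_annotation(cfg)
scores = window_scan(genes, clusters, {"chr1": 10_000_000},
                     window=1_000_000, slide=1_000_000)
top = rank_hotspots(scores)[0]
print(top.window_start, top.window_end, f"{top.score:.4f}")
# -> 4000000 5000000 0.0300
```

The first number is the k-mer genome size rendered at three significant
figures; the second line shows that the window with the planted 20×
elevated clusters-per-gene rate is ranked first, with a density score of
3 clusters / 100 genes = 0.03. The `examples/` directory has one short
narrative script per capability (`genome_size_estimates.py`,
`hotspot_scan.py`, `coexpression_filter.py`, `pairwise_dnds.py`,
`divergence_dating.py`, `pathway_colinearity.py`); each prints the numbers
it computes and says what they mean.

## Command line

A thin CLI wraps the library for shell use:

```bash
bgcpipe simulate annotation --seed 7 --hotspot 0:4000000:5000000:0.05 --outdir run/
bgcpipe density scan --gff run/genes.gff3 --clusters run/clusters.bed \
    --chrom-sizes run/chrom.sizes --window 1000000 --slide 1000000 --outdir run/scan
bgcpipe genome-size flow --sample-mean 8.486 --standard-mean 5.43
bgcpipe dnds --pairs pairs/ --method gy94
bgcpipe run --config pipeline.yaml --outdir run/   # multi-stage, with manifest
```

Exit codes: 0 ok, 2 bad input, 3 numerical failure. `bgcpipe run` writes a
`manifest.json` with the package version, configuration echo and SHA-256
checksums of all inputs; identical configuration and seeds give
byte-identical outputs.

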