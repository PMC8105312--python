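# Methods

This note documents the models behind each `bgcpipe` module, the
parameters that matter, the numerical choices, and what the synthetic
data does and does not emulate.

## Cluster density scanning (`bgcpipe.density`)

The density score of a genomic window is the number of cluster calls
divided by the number of genes whose midpoints fall in the window
(clusters per gene). Normalising by gene count rather than by window
length prevents gene-poor regions (pericentromeres, terminal windows)
from being under- or over-called purely through gene density.

Windows start at 0 and advance by the slide while the start is inside
the chromosome; the last windows are truncated at the chromosome end
and kept — subtelomeric hotspots live precisely in such windows, and
the per-gene normalisation handles their smaller counts. Defaults are
a 100 Mb window with a 10 Mb slide, appropriate for multi-Gb cereal
genomes; toy analyses scale both down together (all counts and scores
are invariant under jointly rescaling coordinates, window and slide).

**Midpoint assignment.** A feature belongs to a window iff its midpoint
lies in `[start, end)`. This makes every disjoint tiling a partition of
the features (tested), makes each feature contribute to exactly
`window/slide` overlapping windows, and avoids the ambiguity of
overlap- or containment-based counting for clusters that straddle
window edges. Whether one counts by midpoint, overlap or containment
is a genuine free choice; midpoint is ours and is documented
everywhere the score is reported.

Ranking is by descending score with deterministic tie-breaking (higher
cluster count, then chromosome name, then window start). Windows with
zero genes have an undefined score and are excluded from ranking.

The co-expression filter on top of the scan flags a cluster when at
least `min_genes` (default 3) member genes, bait included, have
Pearson r strictly above `r_threshold` (default 0.85). The inequality
is strict, so r = 0.85 exactly does not pass.

## Co-expression (`bgcpipe.coexpression`)

Size factors use the median-of-ratios estimator: for sample *j*,
`factor_j = median_i( counts_ij / geomean_i )` over genes *i* with all
counts positive (the geometric mean is taken across samples). This is
the DESeq2 normalisation, reimplemented here because only the size
factors are needed. The median is taken in linear space; note that
scaling one sample's counts by *c* shifts every gene's geometric mean
by c^(1/m), so individual factors transform as c^((m−1)/m) and
c^(−1/m) — only factor *ratios* are equivariant, which is what the
tests assert.

Correlations are computed on normalised counts without a log
transform by default (a `log2(x+1)` option exists); replicates are
treated as separate samples rather than averaged, so six tissues with
two replicates give n = 12 points per correlation. The bait gene of a
cluster defaults to the member with the highest mean normalised
expression (ties broken lexicographically) and can be overridden.
Zero-variance genes get an undefined correlation and never count
toward the filter; a zero-variance bait is an error.

Z-score matrices standardise each gene across samples with the n−1
sample standard deviation (the common heatmap convention); constant
genes are emitted as zero rows with a flag rather than dividing by
zero.

## Genome size (`bgcpipe.genome_size`)

**k-mer route.** With `Kn` the total number of k-mer instances, `Ku`
the instances observed exactly once (treated as sequencing errors) and
`Dp` the depth of the main coverage peak, the haploid genome size is
`Gs = (Kn − Ku)/Dp`. Only occurrence-1 k-mers are subtracted;
occurrence-2 k-mers stay in the numerator, matching the published oat
arithmetic this module reproduces ((124,199,810,495 −
12,260,521,110)/29 → 3.86 Gb at three significant figures).

Peak detection takes the argmax of the histogram at or above a
cutoff. In `auto` mode the cutoff is the first strict local minimum
above occurrence 1 (the error/coverage valley, ties toward the lower
occurrence); a histogram that rises from its first bin has no error
component and uses its first occurrence; a monotonically decreasing
histogram has no detectable peak and raises, suggesting an explicit
cutoff.

Mode-based estimation carries an inherent granularity: the peak is an
integer, so the estimate is quantised in units of Dp. At integer mean
depth λ the Poisson depth distribution has tied modes at λ−1 and λ,
and the detected peak falls on either with roughly equal probability,
giving a λ/(λ−1) relative error (3.4% at λ=30) on about half of
datasets. Round-trip tests therefore simulate at non-integer coverage,
where the mode is unique. Real spectra, with overdispersed depth, are
less affected but not immune; heterozygosity and repeat structure
(GenomeScope-style mixture modelling) are out of scope.

**Flow-cytometry route.** `2C_pg = (sample G1 mean / standard G1 mean)
× standard 2C`, with the maize standard 2C = 5.43 pg as default, and
`1C_bp = (2C_pg / 2) × 0.978e9`. The function is exact arithmetic;
measurement error lives in the inputs.

## Codon evolution (`bgcpipe.codon`)

**NG86.** Expected synonymous site counts per codon are the fraction
of the nine single-nucleotide neighbours that are synonymous, with a
denominator of 3 per position (the classic convention); changes to
stop codons are not synonymous and therefore count toward N. Observed
differences average over all minimal substitution pathways between two
codons with equal weights, excluding pathways that pass through a stop
codon (if every pathway is blocked, all are used with stop-adjacent
steps counted as nonsynonymous). Proportions `pS = Sd/S̄`, `pN = Nd/N̄`
(sites averaged over the two sequences) are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − 4p/3)`; p ≥ 3/4 saturates to +∞ with a flag so
batch runs complete. ω = dN/dS is undefined when dS = 0.

Because NG86 is a counting method, absolute Ks can differ from
model-averaged estimators by a few percent; it is used here for its
transparency (every number is reproducible by hand enumeration, as the
TTT/GTT test does).

**GY94 maximum likelihood.** The rate matrix over the 61 sense codons
has `q_ij = π_j · κ^[transition] · ω^[nonsynonymous]` for
single-nucleotide changes and zero otherwise, scaled so the expected
rate `−Σ π_i q_ii = 1`; branch length t is therefore in expected
substitutions per codon. Codon frequencies default to F3x4 (positional
nucleotide frequencies from the concatenated pair, floored at 1e-8 and
renormalised); equal frequencies are available and are what the
simulator uses by default.

For an unrooted pair the likelihood is
`ℓ = Σ_sites log( π_a · P_{a→b}(t) )`, computed from the 61×61 site
pattern count matrix. P(t) uses the reversibility of the chain: with
D = diag(π), `D^{1/2} Q D^{-1/2}` is symmetric, one `eigh` gives P(t)
for any t cheaply. Tests verify this against `scipy.linalg.expm`
(Padé scaling-and-squaring) to 1e-6 and better.

Optimisation is L-BFGS-B on log-parameters (bounds t ∈ [1e-6, 50],
κ ∈ [0.01, 100], ω ∈ [1e-4, 20]) from four fixed starting points; the
best log-likelihood wins, ties toward smaller t. With ω fixed (the
null fit) only (t, κ) are optimised. Identical sequences drive t to
its lower bound with ℓ ≈ Σ log π, the expected degenerate optimum.

**LRT.** `stat = 2(ℓ_free − ℓ_fixed)`, clamped at zero for numerical
noise, compared to the upper tail of χ²(1); significance at p < 0.05.
ω = 1 is interior to the parameter space, so the plain χ²(1) reference
(no boundary mixture) is correct, and simulation confirms the type-I
error sits at the nominal 5% when the fitted frequencies match the
generating ones. Fitting F3x4 frequencies to equal-frequency data
makes the test mildly conservative — ordinary misspecification
behaviour. A free fit below the fixed fit by more than 1e-6 raises an
optimizer-failure error rather than reporting a negative statistic.

**Dating.** `T = mean_Ks / (2r)`: substitutions accrue on both
lineages since the split. The default r = 6.5e-9 synonymous
substitutions per site per year is a standard grass rate; with it,
mean Ks 0.3705 dates a split at 28.5 My. The factor of 2 is the
standard reading for pairwise divergence and is stated explicitly
wherever times are reported.

## Colinearity (`bgcpipe.colinearity`)

The qualitative observation that cluster gene order can track pathway
step order is made testable as Kendall's tau-b between each gene's
distance from a stated telomere end and its pathway step rank. Tau-b
handles the tied ranks that parallel pathway steps produce, and a
short 12-gene ordering gives too few distinct values for asymptotic
p-values to be trusted, hence a two-sided permutation test:
`p = (1 + #{|τ*| ≥ |τ|}) / (1 + n_perm)` over uniform permutations of
the ranks under a mandatory seed. Reports carry a note that the
statistic is this package's construction.

## Synthetic data (`bgcpipe.simulate`)

All generators are deterministic under their seed (tested to
byte-identity through the pipeline writers).

**Annotation.** Each chromosome is divided into equal slots, one gene
per slot, so genes are sorted and non-overlapping by construction.
Every gene draws an independent Bernoulli trial at its local
clusters-per-gene rate (background 0.002, or the elevated hotspot rate
inside the planted interval); a success plants a cluster call spanning
that gene and the next two, so every call covers ≥3 consecutive genes.
The expected cluster count in a region is rate × genes, which the
tests check within 3 binomial SDs. What this does not emulate: real
gene-density gradients along chromosomes, nested/overlapping clusters,
or cluster-type mixtures — the scan consumes calls as given, so these
do not affect its correctness, only realism.

**Expression.** Counts are negative binomial with variance
μ + αμ² (dispersion α = 0.05 by default, a typical well-replicated
bulk RNA-seq scale). Background genes draw a log-normal baseline
(median 50 counts) and independent log-normal per-tissue effects
(log-SD 1.0), so they are uncorrelated with the planted module.
Planted genes share one per-tissue mean profile (default
root-tip-high: 40/400/5/10/8/6 across six tissues, two replicates
each) up to a per-gene log-normal amplitude — Pearson r is invariant
to that scaling. Library sizes multiply each sample by a factor drawn
from U(0.7, 1.4). The published experiment behind this design gives
no dispersion or library-size characteristics, so these defaults were
chosen once for realism and testability; passing the planted-recovery
tests shows the filter works at this noise level, not at every noise
level a real experiment might show (batch effects, outlier samples
and count-model misspecification are not simulated).

**k-mer spectrum.** Simulated directly as a histogram: each distinct
genomic k-mer draws a Poisson depth at the configured coverage, a
`repeat_fraction` of the genome collapses into two-copy words at
doubled depth, and error words contribute a configurable fraction of
all instances at occurrence 1–2 (80/20). Read-level simulation is
deliberately avoided — the estimator consumes only the histogram.
Coverage must exceed 2 or the coverage peak is indistinguishable from
the error component.

**Codon pairs.** The ancestor is drawn site-wise from π and the
descendant from the exact P(t) = exp(Qt) row of the GY94 matrix —
matrix-exponential sampling per site, no approximation — so simulated
pairs are exact draws from the model the fitter assumes, and
parameter-recovery bands are meaningful.

## Pipeline and CLI

`run_pipeline` executes stages in a fixed order from a flat declarative
config, validates that every referenced input exists before any work,
and writes a manifest (package version, config echo, SHA-256 input
checksums). When annotation and expression are simulated in the same
run, the count matrix reuses the annotation's gene ids and the planted
co-expression module is placed on one cluster call (preferring one
inside the hotspot), so the density and co-expression stages share a
coherent planted truth. The CLI is a thin wrapper; exit code 2 marks
input errors and 3 numerical failures.

## Problem sizes

Default test and acceptance problem sizes — 10 Mb/1000-gene toy
chromosomes, 500 × 12 count matrices, 300–500-codon pairs, 50-seed
recovery and 200-replicate calibration runs, 1000 density-oracle
trials — were chosen so the full suite completes in a few minutes on
one core while leaving each statistical check enough power to fail
visibly if the implementation drifts (e.g. 3-binomial-SD bands).

## Known limitations

* NG86 Ks differs from model-averaged Ks estimators by a few percent
  at moderate divergence; dating inherits this plus the (larger)
  uncertainty of the clock rate itself.
* The pairwise GY94 fit estimates κ and ω per pair; short pairs
  (≲100 codons) give noisy ω̂, and saturated pairs should be filtered
  on the NG86 saturation flag first.
* The k-mer estimator has the mode-granularity bias described above
  and no heterozygosity/repeat mixture model.
* The colinearity permutation test is exchangeable only under the
  null of no association between position and rank; gene-order
  autocorrelation within tandem arrays would violate it.
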