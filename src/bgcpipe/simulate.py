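"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed and emulates one of
the analysis inputs:

* a multi-chromosome gene annotation with cluster calls planted at a
  background rate everywhere and an elevated rate inside one hotspot
  interval (the planted truth for the density scan);
* a tissue-structured negative-binomial count matrix with one planted
  co-expressed gene set (the planted truth for the co-expression
  filter);
* a k-mer occurrence spectrum with an error component at occurrence
  1-2 and a coverage peak (input for genome-size estimation);
* codon sequence pairs evolved under the GY94 model with known
  t, kappa and omega (the oracle for the ML fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import (
    SENSE_CODONS,
    CodonPair,
    build_rate_matrix,
    equal_frequencies,
    transition_matrix,
)
from .coexpression import CountMatrix
from .density import ClusterCall, GeneRecord
from .genome_size import KmerSpectrum

__all__ = [
    "AnnotationSimConfig",
    "ExpressionSimConfig",
    "SpectrumSimConfig",
    "gen_annotation",
    "gen_expression",
    "gen_kmer_spectrum",
    "simulate_codon_pair",
]


# ---------------------------------------------------------------------------
# annotation + cluster calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationSimConfig:
    """Genome layout for the planted-hotspot density simulation.

    ``hotspot`` is (chromosome index, (start, end) in bp, elevated
    clusters-per-gene rate); genes inside the interval seed cluster
    calls at the elevated rate, all others at ``background_cluster_rate``.
    """

    chromosome_lengths: tuple[int, ...]
    n_genes: tuple[int, ...]  # per chromosome
    background_cluster_rate: float = 0.002
    hotspot: tuple[int, tuple[int, int], float] | None = None
    seed: int = 0
    cluster_span_genes: int = 3  # consecutive genes per planted cluster

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) != len(self.n_genes):
            raise ValueError("one gene count per chromosome required")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if not 0 <= self.background_cluster_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.cluster_span_genes < 3:
            raise ValueError("clusters must span >= 3 consecutive genes")
        if self.hotspot is not None:
            ci, (s, e), rate = self.hotspot
            if not 0 <= ci < len(self.chromosome_lengths):
                raise ValueError("hotspot chromosome index out of range")
            if not (0 <= s < e <= self.chromosome_lengths[ci]):
                raise ValueError("hotspot interval outside its chromosome")
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


def gen_annotation(
    config: AnnotationSimConfig,
) -> tuple[list[GeneRecord], list[ClusterCall]]:
    """Generate sorted, non-overlapping genes and planted cluster calls.

    Each chromosome is divided into equal slots, one gene per slot, so
    gene intervals never overlap. Every gene draws a Bernoulli trial at
    its local clusters-per-gene rate; a success plants one cluster call
    spanning that gene and the next ``cluster_span_genes - 1`` genes.
    """
    rng = np.random.default_rng(config.seed)
    genes: list[GeneRecord] = []
    clusters: list[ClusterCall] = []
    for ci, (length, n) in enumerate(zip(config.chromosome_lengths, config.n_genes)):
        chrom = f"chr{ci + 1}"
        slot = length // n
        if slot < 10:
            raise ValueError(f"{chrom}: too many genes for its length")
        glen = max(2, min(3000, slot // 2))
        starts = np.arange(n, dtype=np.int64) * slot + rng.integers(0, slot - glen, size=n)
        chrom_genes = [
            GeneRecord(
                chrom=chrom,
                start=int(s),
                end=int(s + glen),
                strand="+" if rng.random() < 0.5 else "-",
                gene_id=f"{chrom}_g{k:05d}",
            )
            for k, s in enumerate(starts)
        ]
        genes.extend(chrom_genes)

        span = config.cluster_span_genes
        for k, g in enumerate(chrom_genes[: max(0, n - span + 1)]):
            rate = config.background_cluster_rate
            if config.hotspot is not None:
                hci, (hs, he), hrate = config.hotspot
                if hci == ci and hs <= g.midpoint < he:
                    rate = hrate
            if rate > 0 and rng.random() < rate:
                members = chrom_genes[k : k + span]
                clusters.append(
                    ClusterCall(
                        chrom=chrom,
                        start=members[0].start,
                        end=members[-1].end,
                        cluster_id=f"{chrom}_c{len(clusters):04d}",
                        cluster_type="triterpene",
                        member_gene_ids=tuple(m.gene_id for m in members),
                    )
                )
    return genes, clusters


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Negative-binomial count matrix with one planted co-expressed set.

    Background genes draw independent per-tissue means (log-normal
    tissue effects around a gene baseline), so they are uncorrelated
    with the planted profile. Planted genes share ``planted_profile``
    (per-tissue means) up to a per-gene amplitude. Counts follow
    NB(mean mu, dispersion alpha) with variance mu + alpha mu^2, then
    each sample is scaled by a drawn library-size factor.
    """

    n_genes: int = 500
    tissues: tuple[tuple[str, int], ...] = (
        ("root", 2),
        ("roottip", 2),
        ("leaf", 2),
        ("panicle", 2),
        ("shoot", 2),
        ("spikelet", 2),
    )
    planted_cluster_genes: tuple[str, ...] = tuple(f"gene{k:04d}" for k in range(8))
    planted_profile: tuple[float, ...] = (40.0, 400.0, 5.0, 10.0, 8.0, 6.0)
    dispersion: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    background_mean: float = 50.0
    tissue_effect_sd: float = 1.0  # log-scale SD of background tissue effects
    gene_ids: tuple[str, ...] | None = None  # override the default gene0000.. ids
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids must have length n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not self.planted_cluster_genes:
            raise ValueError("planted gene set must be non-empty")
        if self.size_factor_range[0] <= 0:
            raise ValueError("size factors must be > 0")
        if any(reps < 1 for _, reps in self.tissues):
            raise ValueError("each tissue needs >= 1 replicate")
        if len(self.planted_profile) != len(self.tissues):
            raise ValueError("planted profile must give one mean per tissue")
        if self.n_genes < len(self.planted_cluster_genes):
            raise ValueError("n_genes smaller than the planted set")


def gen_expression(config: ExpressionSimConfig) -> CountMatrix:
    """Simulate a genes x samples count matrix per the config."""
    rng = np.random.default_rng(config.seed)
    if config.gene_ids is not None:
        gene_ids = list(config.gene_ids)
    else:
        gene_ids = [f"gene{k:04d}" for k in range(config.n_genes)]
    planted = set(config.planted_cluster_genes)
    unknown = planted - set(gene_ids)
    if unknown:
        raise ValueError(f"planted genes outside the gene-id space: {sorted(unknown)}")

    sample_ids = [f"{t}_{r + 1}" for t, reps in config.tissues for r in range(reps)]
    tissue_of_sample = [ti for ti, (_, reps) in enumerate(config.tissues) for _ in range(reps)]
    n_tissues = len(config.tissues)

    # per-gene per-tissue means
    means = np.empty((config.n_genes, n_tissues))
    profile = np.asarray(config.planted_profile, dtype=float)
    for gi, gid in enumerate(gene_ids):
        if gid in planted:
            amp = rng.lognormal(mean=0.0, sigma=0.25)
            means[gi] = profile * amp
        else:
            base = rng.lognormal(mean=np.log(config.background_mean), sigma=0.8)
            effects = rng.lognormal(mean=0.0, sigma=config.tissue_effect_sd, size=n_tissues)
            means[gi] = base * effects

    sf = rng.uniform(*config.size_factor_range, size=len(sample_ids))
    mu = means[:, tissue_of_sample] * sf[None, :]
    # NB(mean mu, dispersion alpha): shape n = 1/alpha, p = n / (n + mu)
    n_shape = 1.0 / config.dispersion
    counts = rng.negative_binomial(n_shape, n_shape / (n_shape + mu))
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    return CountMatrix(counts=df)


# ---------------------------------------------------------------------------
# k-mer spectrum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumSimConfig:
    """k-mer spectrum model: Poisson depth per distinct k-mer.

    Unique genome k-mers draw occurrence ~ Poisson(coverage); a
    ``repeat_fraction`` of the genome collapses into two-copy k-mers at
    doubled depth; error k-mers contribute a fraction
    ``error_kmer_fraction`` of all k-mer instances at occurrence 1-2.
    """

    genome_size: int = 1_000_000
    coverage: float = 30.0
    error_kmer_fraction: float = 0.0
    repeat_fraction: float = 0.0
    k: int = 55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        if self.coverage <= 2:
            raise ValueError(
                "coverage must be > 2 (coverage peak indistinguishable from errors)"
            )
        if not (0 <= self.error_kmer_fraction < 1 and 0 <= self.repeat_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")


def gen_kmer_spectrum(config: SpectrumSimConfig) -> KmerSpectrum:
    """Simulate a k-mer occurrence histogram per the config."""
    rng = np.random.default_rng(config.seed)
    n_repeat_bp = int(round(config.genome_size * config.repeat_fraction))
    n_unique = config.genome_size - n_repeat_bp
    n_repeat_words = n_repeat_bp // 2  # two genomic copies collapse into one word

    occs = [rng.poisson(config.coverage, size=n_unique)]
    if n_repeat_words > 0:
        occs.append(rng.poisson(2.0 * config.coverage, size=n_repeat_words))

    if config.error_kmer_fraction > 0:
        true_instances = config.genome_size * config.coverage
        f = config.error_kmer_fraction
        err_instances = f / (1.0 - f) * true_instances
        # error words occur once (80%) or twice (20%): 1.2 instances/word
        n_err = int(round(err_instances / 1.2))
        occs.append(np.where(rng.random(n_err) < 0.8, 1, 2).astype(np.int64))

    occ = np.concatenate(occs)
    occ = occ[occ >= 1]  # depth-0 k-mers are unobserved
    hist = np.bincount(occ)
    histogram = {int(o): int(c) for o, c in enumerate(hist) if c > 0}
    return KmerSpectrum(k=config.k, histogram=histogram)


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------


def simulate_codon_pair(
    t: float,
    kappa: float,
    omega: float,
    n_codons: int,
    freqs: np.ndarray | str = "equal",
    seed: int = 0,
) -> CodonPair:
    """Evolve a codon pair under GY94 with known parameters.

    The ancestor is drawn site-wise from the stationary distribution
    pi; the descendant is sampled per site from the exact transition
    matrix P(t) = exp(Qt). Branch length t is in expected substitutions
    per codon; at t = 0 the two sequences are identical.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if isinstance(freqs, str):
        if freqs != "equal":
            raise ValueError("freqs must be 'equal' or a 61-probability vector")
        pi = equal_frequencies()
    else:
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
    rng = np.random.default_rng(seed)
    anc = rng.choice(61, size=n_codons, p=pi)
    if t == 0:
        dec = anc.copy()
    else:
        q = build_rate_matrix(kappa, omega, pi)
        p = transition_matrix(q, pi, t)
        p = p / p.sum(axis=1, keepdims=True)
        u = rng.random(n_codons)
        cdf = np.cumsum(p, axis=1)
        dec = np.array([int(np.searchsorted(cdf[a], x)) for a, x in zip(anc, u)])
        dec = np.minimum(dec, 60)
    seq_a = "".join(SENSE_CODONS[i] for i in anc)
    seq_b = "".join(SENSE_CODONS[i] for i in dec)
    return CodonPair(seq_a, seq_b)
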