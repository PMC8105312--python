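import numpy as np
import pytest

import bgcpipe as b


@pytest.fixture(scope="session")
def planted_annotation():
    """1-chromosome 10 Mb genome, 1000 genes, one 1 Mb hotspot at 20x rate."""
    cfg = b.AnnotationSimConfig(
        chromosome_lengths=(10_000_000,),
        n_genes=(1000,),
        background_cluster_rate=0.002,
        hotspot=(0, (4_000_000, 5_000_000), 0.05),
        seed=7,
    )
    genes, clusters = b.gen_annotation(cfg)
    return cfg, genes, clusters


@pytest.fixture(scope="session")
def planted_counts():
    """Six-tissue, two-replicate NB counts with a planted 8-gene module."""
    cfg = b.ExpressionSimConfig(seed=3)
    return cfg, b.gen_expression(cfg)


@pytest.fixture(scope="session")
def small_codon_pair():
    return b.simulate_codon_pair(0.3, 2.0, 0.2, 300, seed=11)


def random_genes_and_clusters(rng, chrom_lengths):
    """Unstructured random features for oracle comparisons."""
    genes, clusters = [], []
    for ci, length in enumerate(chrom_lengths):
        chrom = f"chr{ci + 1}"
        for k in range(rng.integers(20, 80)):
            s = int(rng.integers(0, length - 100))
            e = s + int(rng.integers(1, 100))
            genes.append(b.GeneRecord(chrom, s, min(e, length), "+", f"{chrom}_g{k}"))
        for k in range(rng.integers(0, 10)):
            s = int(rng.integers(0, length - 1000))
            e = s + int(rng.integers(100, 1000))
            clusters.append(b.ClusterCall(chrom, s, min(e, length), f"{chrom}_c{k}"))
    return genes, clusters
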