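"""Sliding-window biosynthetic-gene-cluster density scoring.

A genome annotation (genes) and a set of cluster calls are scanned with
a large sliding window (default 100 Mb, slide 10 Mb). The density score
of a window is the number of cluster calls divided by the number of
genes in the window — cluster density normalised by gene density — so
gene-poor terminal regions are not penalised. Features are assigned to
windows by their midpoint, so any disjoint tiling partitions them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GeneRecord",
    "ClusterCall",
    "WindowScore",
    "window_scan",
    "rank_hotspots",
    "coexpressed_cluster_count",
]


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval. Coordinates are 0-based half-open internally."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class ClusterCall:
    """A predicted biosynthetic gene cluster interval with member genes."""

    chrom: str
    start: int
    end: int
    cluster_id: str
    cluster_type: str = "putative"
    member_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"cluster {self.cluster_id}: start > end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class WindowScore:
    chrom: str
    window_start: int
    window_end: int
    n_clusters: int
    n_genes: int
    score: float  # clusters per gene; NaN when n_genes == 0

    @property
    def defined(self) -> bool:
        return self.n_genes > 0


def _check_features(features, chrom_lengths, kind: str) -> None:
    for f in features:
        if f.chrom not in chrom_lengths:
            raise ValueError(f"{kind} {f!r}: chromosome {f.chrom!r} not in chrom_lengths")
        if f.end > chrom_lengths[f.chrom]:
            name = getattr(f, "gene_id", None) or getattr(f, "cluster_id", "")
            raise ValueError(
                f"{kind} {name!r} extends beyond chromosome "
                f"{f.chrom} length {chrom_lengths[f.chrom]}"
            )


def window_scan(
    genes: list[GeneRecord],
    clusters: list[ClusterCall],
    chrom_lengths: dict[str, int],
    window: int = 100_000_000,
    slide: int = 10_000_000,
) -> list[WindowScore]:
    """Score cluster density in sliding windows across every chromosome.

    Windows start at 0, slide, 2*slide, ... while start < chromosome
    length and are truncated at the chromosome end. A feature belongs to
    a window iff its midpoint lies in [window_start, window_end).
    """
    if not (window >= slide > 0):
        raise ValueError("require window >= slide > 0")
    _check_features(genes, chrom_lengths, "gene")
    _check_features(clusters, chrom_lengths, "cluster")

    gene_mids: dict[str, list[float]] = {c: [] for c in chrom_lengths}
    clus_mids: dict[str, list[float]] = {c: [] for c in chrom_lengths}
    for g in genes:
        gene_mids[g.chrom].append(g.midpoint)
    for c in clusters:
        clus_mids[c.chrom].append(c.midpoint)

    out: list[WindowScore] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        gm = sorted(gene_mids[chrom])
        cm = sorted(clus_mids[chrom])
        start = 0
        while start < length:
            end = min(start + window, length)
            ng = _count_in(gm, start, end)
            nc = _count_in(cm, start, end)
            score = nc / ng if ng > 0 else math.nan
            out.append(WindowScore(chrom, start, end, nc, ng, score))
            start += slide
    return out


def _count_in(sorted_mids: list[float], lo: float, hi: float) -> int:
    import bisect

    return bisect.bisect_left(sorted_mids, hi) - bisect.bisect_left(sorted_mids, lo)


def rank_hotspots(scores: list[WindowScore], top_n: int | None = None) -> list[WindowScore]:
    """Windows with defined scores, sorted by descending density score.

    Ties are broken by higher cluster count, then chromosome name, then
    window start, so the ranking is deterministic.
    """
    if not scores:
        raise ValueError("no window scores supplied")
    defined = [w for w in scores if w.defined]
    if not defined:
        raise ValueError("all windows have undefined scores (no genes)")
    ranked = sorted(
        defined,
        key=lambda w: (-w.score, -w.n_clusters, w.chrom, w.window_start),
    )
    return ranked[:top_n] if top_n is not None else ranked


def coexpressed_cluster_count(
    clusters: list[ClusterCall],
    coexpr: dict[str, "object"],
    r_threshold: float = 0.85,
    min_genes: int = 3,
) -> tuple[int, dict[str, bool]]:
    """Count clusters with at least ``min_genes`` co-expressed members.

    ``coexpr`` maps cluster_id -> CoexpressionResult (bait included in
    its per-gene r, with r(bait, bait) = 1). A cluster is flagged iff at
    least ``min_genes`` of its member genes have r strictly greater
    than ``r_threshold``. Members without a defined r (zero-variance
    genes) never count toward the threshold.
    """
    flags: dict[str, bool] = {}
    for cl in clusters:
        try:
            res = coexpr[cl.cluster_id]
        except KeyError:
            raise ValueError(f"no coexpression result for cluster {cl.cluster_id}")
        n_pass = 0
        for gid in cl.member_gene_ids:
            r = res.r.get(gid)
            if r is not None and not math.isnan(r) and r > r_threshold:
                n_pass += 1
        flags[cl.cluster_id] = n_pass >= min_genes
    return sum(flags.values()), flags
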