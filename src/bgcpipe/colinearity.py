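"""Pathway colinearity: does gene order track biosynthetic step order?

In several characterised plant biosynthetic gene clusters the genomic
order of the genes loosely follows the order of the pathway steps they
encode, with early steps nearest the telomere. This module turns that
qualitative observation into a statistic: Kendall's tau-b between each
gene's distance from the telomere and its pathway step rank, with a
two-sided permutation p-value over random reassignments of the ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .density import GeneRecord

__all__ = ["ColinearityResult", "colinearity"]


@dataclass(frozen=True)
class ColinearityResult:
    tau: float  # Kendall tau-b, position rank vs pathway rank
    p_perm: float  # two-sided permutation p-value
    n_genes: int
    orientation: str  # "toward_telomere" | "away"


def colinearity(
    genes: list[GeneRecord],
    order: dict[str, int],
    n_perm: int = 9999,
    seed: int = 0,
    telomere: str = "end",
    chrom_length: int | None = None,
) -> ColinearityResult:
    """Kendall tau-b between telomere distance and pathway rank.

    ``telomere`` says which end of the chromosome the telomere of
    interest is at: "start" (position 0) or "end" (requires
    ``chrom_length``). Only genes present in ``order`` are used; at
    least 3 are required. p_perm = (1 + #{|tau*| >= |tau|}) / (1 + n_perm)
    over uniform permutations of the pathway ranks.
    """
    used = [g for g in genes if g.gene_id in order]
    if len(used) < 3:
        raise ValueError("need >= 3 genes with both a position and a pathway rank")
    chroms = {g.chrom for g in used}
    if len(chroms) > 1:
        raise ValueError(f"genes span multiple chromosomes: {sorted(chroms)}")
    ranks = np.array([order[g.gene_id] for g in used], dtype=float)
    if np.ptp(ranks) == 0:
        raise ValueError("all pathway ranks are tied")
    mids = np.array([g.midpoint for g in used])
    if telomere == "start":
        dist = mids
    elif telomere == "end":
        if chrom_length is None:
            raise ValueError("telomere='end' requires chrom_length")
        dist = chrom_length - mids
    else:
        raise ValueError("telomere must be 'start' or 'end'")

    tau = float(stats.kendalltau(dist, ranks).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        tau_p = stats.kendalltau(dist, perm).statistic
        if abs(tau_p) >= abs(tau) - 1e-12:
            hits += 1
    p_perm = (1 + hits) / (1 + n_perm)
    orientation = "toward_telomere" if tau >= 0 else "away"
    return ColinearityResult(tau=tau, p_perm=p_perm, n_genes=len(used), orientation=orientation)
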