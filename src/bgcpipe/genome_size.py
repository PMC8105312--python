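"""Haploid genome-size estimation from k-mer spectra and flow cytometry.

Two independent estimators are provided:

* **k-mer spectrum**: given the histogram of distinct k-mer words per
  occurrence (depth) class, the haploid genome size is
  ``Gs = (Kn - Ku) / Dp`` where ``Kn`` is the total number of k-mer
  instances, ``Ku`` the number of instances seen exactly once (presumed
  sequencing errors) and ``Dp`` the depth at the main coverage peak.
* **flow cytometry**: the 2C DNA amount of a sample is obtained from the
  ratio of its G1 fluorescence peak mean to that of an internal standard
  of known 2C content, and converted to base pairs with
  1 pg DNA = 0.978e9 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KmerSpectrum",
    "GenomeSizeEstimate",
    "FlowCytometryMeasurement",
    "kmer_totals",
    "detect_peak",
    "estimate_genome_size_from_totals",
    "estimate_genome_size_kmer",
    "flow_cytometry_size",
    "PG_TO_BP",
]

#: base pairs per picogram of DNA (Doležel conversion factor)
PG_TO_BP = 0.978e9


@dataclass(frozen=True)
class KmerSpectrum:
    """Histogram of distinct k-mer words by occurrence (depth) class.

    Parameters
    ----------
    k
        Word length in nucleotides.
    histogram
        Mapping occurrence (integer >= 1) -> number of distinct k-mer
        words observed at exactly that occurrence.
    """

    k: int
    histogram: dict[int, int]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.histogram:
            raise ValueError("spectrum histogram is empty")
        for occ, cnt in self.histogram.items():
            if occ < 1:
                raise ValueError(f"occurrence {occ} < 1")
            if cnt < 0:
                raise ValueError(f"negative count at occurrence {occ}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (occurrences, counts) sorted by occurrence."""
        occ = np.array(sorted(self.histogram), dtype=np.int64)
        cnt = np.array([self.histogram[o] for o in occ], dtype=np.int64)
        return occ, cnt


@dataclass(frozen=True)
class FlowCytometryMeasurement:
    """G1 peak means of a sample and an internal standard of known size."""

    sample_g1_mean: float
    standard_g1_mean: float
    standard_2c_pg: float = 5.43  # maize CE-777 internal standard

    def __post_init__(self) -> None:
        if min(self.sample_g1_mean, self.standard_g1_mean, self.standard_2c_pg) <= 0:
            raise ValueError("flow-cytometry peak means and standard 2C must be > 0")


@dataclass(frozen=True)
class GenomeSizeEstimate:
    genome_size: float  # bp, 1C
    method: str  # "kmer" | "flow_cytometry"
    peak_depth: int | None = None
    inputs_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome_size < 0:
            raise ValueError("genome size must be >= 0")

    @property
    def gigabases(self) -> float:
        return self.genome_size / 1e9

    def format_gb(self, sig: int = 3) -> str:
        """Render in Gb at ``sig`` significant figures (default 3)."""
        return f"{float(f'%.{sig}g' % self.gigabases):g} Gb"


def kmer_totals(spectrum: KmerSpectrum) -> tuple[int, int]:
    """Total (Kn) and unique (Ku) k-mer instances of a spectrum.

    Kn sums occurrence x count over every histogram bin; Ku is the
    number of k-mer instances seen exactly once (histogram[1]).
    """
    occ, cnt = spectrum.as_arrays()
    kn = int(np.sum(occ * cnt))
    ku = int(spectrum.histogram.get(1, 0))
    return kn, ku


def detect_peak(spectrum: KmerSpectrum, min_occurrence: int | str = "auto") -> int:
    """Depth of the main coverage peak, Dp.

    With ``min_occurrence="auto"`` the error/coverage valley is located
    first: the smallest occurrence above 1 that is a strict local
    minimum of the histogram (ties broken toward lower occurrence);
    the peak is then the occurrence with the largest count at or above
    that valley. An explicit ``min_occurrence`` skips valley detection.
    """
    occ, cnt = spectrum.as_arrays()
    if min_occurrence == "auto":
        if len(occ) == 1:
            return int(occ[0])
        if cnt[0] <= cnt[1]:
            # rising (or flat) leading edge: no error component to the left
            valley = occ[0]
        else:
            valley = None
            for i in range(1, len(occ) - 1):
                if cnt[i - 1] > cnt[i] and cnt[i] < cnt[i + 1]:
                    valley = occ[i]
                    break
            if valley is None:
                raise ValueError(
                    "no coverage peak detected: histogram has no error/coverage "
                    "valley; pass an explicit min_occurrence"
                )
        min_occurrence = int(valley)
    mask = occ >= int(min_occurrence)
    if not mask.any():
        raise ValueError(f"no occurrence >= min_occurrence ({min_occurrence})")
    occ, cnt = occ[mask], cnt[mask]
    return int(occ[int(np.argmax(cnt))])


def estimate_genome_size_from_totals(kn: int, ku: int, dp: int) -> GenomeSizeEstimate:
    """Genome size as (Kn - Ku) / Dp from pre-computed spectrum totals.

    Singleton k-mer instances (Ku) are treated as sequencing errors and
    subtracted from the total (Kn) before dividing by the peak depth.
    """
    if dp < 1:
        raise ValueError("peak depth must be >= 1")
    if kn <= ku:
        raise ValueError("Kn <= Ku: no multi-copy k-mer signal in spectrum")
    return GenomeSizeEstimate(
        genome_size=(kn - ku) / dp,
        method="kmer",
        peak_depth=int(dp),
        inputs_echo={"Kn": int(kn), "Ku": int(ku), "Dp": int(dp)},
    )


def estimate_genome_size_kmer(
    spectrum: KmerSpectrum,
    peak_override: int | None = None,
    min_occurrence: int | str = "auto",
) -> GenomeSizeEstimate:
    """Genome size as (Kn - Ku) / Dp from a k-mer spectrum."""
    kn, ku = kmer_totals(spectrum)
    if peak_override is not None:
        dp = int(peak_override)
    else:
        dp = detect_peak(spectrum, min_occurrence=min_occurrence)
    est = estimate_genome_size_from_totals(kn, ku, dp)
    est.inputs_echo["k"] = spectrum.k
    return est


def flow_cytometry_size(m: FlowCytometryMeasurement) -> GenomeSizeEstimate:
    """1C genome size in bp from G1 peak means against an internal standard.

    sample 2C pg = (sample mean / standard mean) x standard 2C pg;
    1C bp = (2C pg / 2) x 0.978e9.
    """
    sample_2c_pg = (m.sample_g1_mean / m.standard_g1_mean) * m.standard_2c_pg
    size_bp = (sample_2c_pg / 2.0) * PG_TO_BP
    return GenomeSizeEstimate(
        genome_size=size_bp,
        method="flow_cytometry",
        inputs_echo={
            "sample_g1_mean": m.sample_g1_mean,
            "standard_g1_mean": m.standard_g1_mean,
            "standard_2c_pg": m.standard_2c_pg,
            "sample_2c_pg": sample_2c_pg,
        },
    )
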