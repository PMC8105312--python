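"""Readers and writers for the pipeline's plain-text formats.

Conventions: GFF3 genes are 1-based inclusive on disk and 0-based
half-open in memory; BED cluster calls are native 0-based half-open
with member gene ids from column 7 on; count matrices are TSV with a
header row of ``tissue_replicate`` sample ids; spectra are two-column
TSV (occurrence, distinct k-mer count) allowing '#' comments; codon
pairs are two-record pre-aligned FASTA files.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coexpression import CountMatrix
from .density import ClusterCall, GeneRecord
from .genome_size import KmerSpectrum

__all__ = [
    "read_gff3_genes",
    "write_gff3_genes",
    "read_clusters_bed",
    "write_clusters_bed",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
    "read_codon_pair_fasta",
    "write_codon_pair_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_pathway_order",
]


def read_gff3_genes(path: str | os.PathLike) -> list[GeneRecord]:
    """Gene features from a GFF3 file, converted to 0-based half-open."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneRecord(
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
                gene_id=gid,
            )
        )
    return genes


def write_gff3_genes(path: str | os.PathLike, genes: list[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbgcpipe\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_clusters_bed(path: str | os.PathLike) -> list[ClusterCall]:
    """Cluster calls from BED: chrom start end id score strand members..."""
    clusters = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"BED line needs >= 4 columns: {line!r}")
            ctype = f[4] if len(f) > 4 and f[4] not in (".", "") else "putative"
            members = tuple(m for m in f[6:] if m)
            clusters.append(
                ClusterCall(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    cluster_id=f[3],
                    cluster_type=ctype,
                    member_gene_ids=members,
                )
            )
    return clusters


def write_clusters_bed(path: str | os.PathLike, clusters: list[ClusterCall]) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            cols = [c.chrom, str(c.start), str(c.end), c.cluster_id, c.cluster_type, "."]
            cols.extend(c.member_gene_ids)
            fh.write("\t".join(cols) + "\n")


def read_counts_tsv(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=df)


def write_counts_tsv(path: str | os.PathLike, m: CountMatrix | pd.DataFrame) -> None:
    df = m.counts if isinstance(m, CountMatrix) else m
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_spectrum_tsv(path: str | os.PathLike, k: int = 0) -> KmerSpectrum:
    """Two-column occurrence<TAB>count spectrum; '#' comments allowed.

    ``k`` may be given in a ``# k=55`` comment or via the argument.
    """
    histogram: dict[int, int] = {}
    k_found = k
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("k="):
                    k_found = int(body[2:])
                continue
            occ_s, cnt_s = line.split("\t")[:2]
            histogram[int(occ_s)] = int(cnt_s)
    return KmerSpectrum(k=k_found or 1, histogram=histogram)


def write_spectrum_tsv(path: str | os.PathLike, spectrum: KmerSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# k={spectrum.k}\n# occurrence\tdistinct_kmer_count\n")
        for occ in sorted(spectrum.histogram):
            fh.write(f"{occ}\t{spectrum.histogram[occ]}\n")


def read_codon_pair_fasta(path: str | os.PathLike) -> tuple[str, str, str, str]:
    """(id_a, seq_a, id_b, seq_b) from a two-record pre-aligned FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, got {len(records)}")
    a, b = records
    return a.id, str(a.seq), b.id, str(b.seq)


def write_codon_pair_fasta(
    path: str | os.PathLike, id_a: str, seq_a: str, id_b: str, seq_b: str
) -> None:
    SeqIO.write(
        [
            SeqRecord(Seq(seq_a), id=id_a, description=""),
            SeqRecord(Seq(seq_b), id=id_b, description=""),
        ],
        str(path),
        "fasta",
    )


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes


def write_chrom_sizes(path: str | os.PathLike, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_pathway_order(path: str | os.PathLike) -> dict[str, int]:
    """gene_id<TAB>step_rank table (1 = earliest biosynthetic step)."""
    order: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gid, rank = line.split("\t")[:2]
            r = int(rank)
            if r < 1:
                raise ValueError(f"pathway rank must be >= 1 (gene {gid})")
            order[gid] = r
    return order
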