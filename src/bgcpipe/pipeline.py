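"""Declarative multi-stage pipeline runner with a reproducibility manifest.

A run is described by a flat configuration mapping (usually a YAML
file) with one key per stage. Stages execute in a fixed order
(simulate -> genome_size -> density -> coexpr -> dnds -> date ->
colinearity), each writing TSV/JSON outputs into the run directory,
and a manifest records the package version, seeds, the configuration
echo and SHA-256 checksums of every input file. Identical
configuration and seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as pio
from .codon import clean_alignment, divergence_time, gy94_fit, lrt, ng86
from .coexpression import bait_correlation, normalize, select_bait, size_factors
from .colinearity import colinearity
from .density import coexpressed_cluster_count, rank_hotspots, window_scan
from .genome_size import (
    FlowCytometryMeasurement,
    estimate_genome_size_from_totals,
    estimate_genome_size_kmer,
    flow_cytometry_size,
)
from .simulate import (
    AnnotationSimConfig,
    ExpressionSimConfig,
    SpectrumSimConfig,
    gen_annotation,
    gen_expression,
    gen_kmer_spectrum,
)

__all__ = ["run_pipeline", "STAGE_ORDER"]

STAGE_ORDER = ("simulate", "genome_size", "density", "coexpr", "dnds", "date", "colinearity")


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_inputs(config: dict) -> list[str]:
    """Collect every referenced input path; error before any work."""
    paths = []
    for stage, params in config.items():
        if stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGE_ORDER}")
        if not isinstance(params, dict):
            raise ValueError(f"stage {stage!r}: parameters must be a mapping")
        for key, val in params.items():
            if key.endswith(("_file", "_dir", "_gff", "_bed", "_tsv")):
                if not Path(val).exists():
                    raise ValueError(f"stage {stage!r}: missing input {key}={val!r}")
                paths.append(str(val))
    return paths


def run_pipeline(config: dict, outdir: str | os.PathLike) -> dict:
    """Execute the requested stages and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    input_paths = _require_inputs(config)
    manifest: dict = {
        "bgcpipe_version": __version__,
        "config": config,
        "input_checksums": {p: _sha256(p) for p in input_paths},
        "outputs": {},
    }

    sim_artifacts: dict = {}
    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        params = dict(config[stage])
        handler = _STAGES[stage]
        outputs = handler(params, outdir, sim_artifacts)
        manifest["outputs"][stage] = outputs

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# stage handlers: params -> list of output files written
# ---------------------------------------------------------------------------


def _stage_simulate(params: dict, outdir: Path, artifacts: dict) -> list[str]:
    written = []
    if "annotation" in params:
        cfg = AnnotationSimConfig(**_tuplify(params["annotation"]))
        genes, clusters = gen_annotation(cfg)
        pio.write_gff3_genes(outdir / "genes.gff3", genes)
        pio.write_clusters_bed(outdir / "clusters.bed", clusters)
        sizes = {f"chr{i + 1}": l for i, l in enumerate(cfg.chromosome_lengths)}
        pio.write_chrom_sizes(outdir / "chrom.sizes", sizes)
        artifacts["genes"], artifacts["clusters"], artifacts["chrom_sizes"] = genes, clusters, sizes
        written += ["genes.gff3", "clusters.bed", "chrom.sizes"]
    if "expression" in params:
        expr_params = _tuplify(params["expression"])
        if "genes" in artifacts and "gene_ids" not in expr_params:
            # tie the count matrix to the simulated annotation: same gene
            # ids, planted co-expression module = one planted cluster
            # (preferring a cluster inside the hotspot)
            genes = artifacts["genes"]
            clusters = artifacts["clusters"]
            expr_params["gene_ids"] = tuple(g.gene_id for g in genes)
            expr_params["n_genes"] = len(genes)
            if clusters and "planted_cluster_genes" not in expr_params:
                target = clusters[0]
                ann = params.get("annotation", {})
                hotspot = ann.get("hotspot")
                if hotspot is not None:
                    hs_lo, hs_hi = hotspot[1]
                    for cl in clusters:
                        if hs_lo <= cl.midpoint < hs_hi:
                            target = cl
                            break
                expr_params["planted_cluster_genes"] = tuple(target.member_gene_ids)
                artifacts["planted_cluster_id"] = target.cluster_id
        cfg = ExpressionSimConfig(**expr_params)
        cm = gen_expression(cfg)
        pio.write_counts_tsv(outdir / "counts.tsv", cm)
        artifacts["counts"] = cm
        written.append("counts.tsv")
    if "spectrum" in params:
        cfg = SpectrumSimConfig(**params["spectrum"])
        spec = gen_kmer_spectrum(cfg)
        pio.write_spectrum_tsv(outdir / "spectrum.tsv", spec)
        artifacts["spectrum"] = spec
        written.append("spectrum.tsv")
    return written


def _stage_genome_size(params: dict, outdir: Path, artifacts: dict) -> list[str]:
    result: dict = {}
    if "kn" in params:  # direct totals, e.g. from a published table
        kn, ku, dp = int(params["kn"]), int(params["ku"]), int(params["dp"])
        est = estimate_genome_size_from_totals(kn, ku, dp)
        result["kmer"] = {
            "genome_size_bp": est.genome_size,
            "genome_size_gb_3sf": float(f"{est.gigabases:.3g}"),
            "peak_depth": dp,
            "inputs_echo": est.inputs_echo,
        }
    elif "spectrum_file" in params or "spectrum" in artifacts:
        spec = (
            pio.read_spectrum_tsv(params["spectrum_file"])
            if "spectrum_file" in params
            else artifacts["spectrum"]
        )
        est = estimate_genome_size_kmer(
            spec,
            peak_override=params.get("peak"),
            min_occurrence=params.get("min_occurrence", "auto"),
        )
        result["kmer"] = {
            "genome_size_bp": est.genome_size,
            "genome_size_gb_3sf": float(f"{est.gigabases:.3g}"),
            "peak_depth": est.peak_depth,
            "inputs_echo": est.inputs_echo,
        }
    if "sample_mean" in params:
        m = FlowCytometryMeasurement(
            sample_g1_mean=float(params["sample_mean"]),
            standard_g1_mean=float(params["standard_mean"]),
            standard_2c_pg=float(params.get("standard_2c", 5.43)),
        )
        est = flow_cytometry_size(m)
        result["flow_cytometry"] = {
            "genome_size_bp": est.genome_size,
            "genome_size_gb_2sf": float(f"{est.gigabases:.2g}"),
            "inputs_echo": est.inputs_echo,
        }
    if not result:
        raise ValueError("genome_size stage: no inputs (kn/ku/dp, spectrum, or flow means)")
    _write_json(outdir / "genome_size.json", result)
    return ["genome_size.json"]


def _stage_density(params: dict, outdir: Path, artifacts: dict) -> list[str]:
    genes = artifacts.get("genes")
    clusters = artifacts.get("clusters")
    sizes = artifacts.get("chrom_sizes")
    if "genes_gff" in params:
        genes = pio.read_gff3_genes(params["genes_gff"])
    if "clusters_bed" in params:
        clusters = pio.read_clusters_bed(params["clusters_bed"])
    if "chrom_sizes_file" in params:
        sizes = pio.read_chrom_sizes(params["chrom_sizes_file"])
    if genes is None or clusters is None or sizes is None:
        raise ValueError("density stage: needs genes, clusters and chromosome sizes")
    scores = window_scan(
        genes,
        clusters,
        sizes,
        window=int(params.get("window", 100_000_000)),
        slide=int(params.get("slide", 10_000_000)),
    )
    df = pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "window_start": w.window_start,
                "window_end": w.window_end,
                "n_clusters": w.n_clusters,
                "n_genes": w.n_genes,
                "score": w.score,
            }
            for w in scores
        ]
    )
    df.to_csv(outdir / "density_windows.tsv", sep="\t", index=False)
    top = rank_hotspots(scores, top_n=int(params.get("top", 10)))
    pd.DataFrame(
        [
            {
                "rank": i + 1,
                "chrom": w.chrom,
                "window_start": w.window_start,
                "window_end": w.window_end,
                "n_clusters": w.n_clusters,
                "n_genes": w.n_genes,
                "score": w.score,
            }
            for i, w in enumerate(top)
        ]
    ).to_csv(outdir / "density_top.tsv", sep="\t", index=False)
    artifacts["density_top"] = top
    return ["density_windows.tsv", "density_top.tsv"]


def _stage_coexpr(params: dict, outdir: Path, artifacts: dict) -> list[str]:
    cm = artifacts.get("counts")
    clusters = artifacts.get("clusters")
    if "counts_tsv" in params:
        cm = pio.read_counts_tsv(params["counts_tsv"])
    if "clusters_bed" in params:
        clusters = pio.read_clusters_bed(params["clusters_bed"])
    if cm is None or clusters is None:
        raise ValueError("coexpr stage: needs a count matrix and cluster calls")
    factors = size_factors(cm, pseudocount=float(params.get("pseudocount", 0.0)))
    norm = normalize(cm, factors)
    r_threshold = float(params.get("r_threshold", 0.85))
    min_genes = int(params.get("min_genes", 3))
    explicit_bait = params.get("bait")
    results = {}
    rows = []
    for cl in clusters:
        members = [g for g in cl.member_gene_ids if g in norm.index]
        if not members:
            continue
        bait = explicit_bait if explicit_bait in members else select_bait(norm, members)
        res = bait_correlation(norm, bait, members)
        results[cl.cluster_id] = res
        n_pass = sum(
            1 for g in members if not math.isnan(res.r[g]) and res.r[g] > r_threshold
        )
        rows.append(
            {"cluster_id": cl.cluster_id, "bait": bait, "n_members": len(members), "n_pass": n_pass}
        )
    usable = [cl for cl in clusters if cl.cluster_id in results]
    total, flags = coexpressed_cluster_count(
        usable, results, r_threshold=r_threshold, min_genes=min_genes
    )
    for row in rows:
        row["flagged"] = flags[row["cluster_id"]]
    pd.DataFrame(rows).to_csv(outdir / "coexpr_clusters.tsv", sep="\t", index=False)
    _write_json(
        outdir / "coexpr_summary.json",
        {"n_clusters": len(rows), "n_coexpressed": total, "r_threshold": r_threshold,
         "min_genes": min_genes},
    )
    artifacts["coexpr_flags"] = flags
    return ["coexpr_clusters.tsv", "coexpr_summary.json"]


def _stage_dnds(params: dict, outdir: Path, artifacts: dict) -> list[str]:
    pairs_dir = Path(params["pairs_dir"])
    method = params.get("method", "gy94")
    freqs = params.get("freqs", "f3x4")
    rows = []
    for path in sorted(pairs_dir.glob("*.fa*")):
        id_a, seq_a, _, seq_b = pio.read_codon_pair_fasta(path)
        pair = clean_alignment(seq_a, seq_b)
        row: dict = {"pair_id": path.stem}
        rates = ng86(pair)
        row.update(
            S=rates.S_sites, N=rates.N_sites, dS=rates.dS, dN=rates.dN,
            omega_ng86=rates.omega if rates.omega is not None else float("nan"),
        )
        if method == "gy94":
            free = gy94_fit(pair, freqs=freqs)
            fixed = gy94_fit(pair, fix_omega=1.0, freqs=freqs)
            res = lrt(free, fixed)
            row.update(
                t=free.t_hat, kappa=free.kappa_hat, omega=free.omega_hat,
                logL_free=free.logL, logL_fixed=fixed.logL,
                lrt_stat=res.stat, p=res.p, significant=res.significant,
            )
        rows.append(row)
    if not rows:
        raise ValueError(f"dnds stage: no pair FASTA files in {pairs_dir}")
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "dnds.tsv", sep="\t", index=False)
    artifacts["dnds"] = df
    return ["dnds.tsv"]


def _stage_date(params: dict, outdir: Path, artifacts: dict) -> list[str]:
    rate = float(params.get("rate", 6.5e-9))
    if "ks_table_file" in params:
        ks = pd.read_csv(params["ks_table_file"], sep="\t")
    elif "dnds" in artifacts:
        ks = artifacts["dnds"][["pair_id", "dS"]].rename(columns={"dS": "Ks"})
    else:
        raise ValueError("date stage: needs ks_table_file or a prior dnds stage")
    ks_col = "Ks" if "Ks" in ks.columns else ks.columns[-1]
    finite = ks[ks_col][pd.notna(ks[ks_col]) & (ks[ks_col] < float("inf"))]
    est = divergence_time(float(finite.mean()), rate=rate)
    _write_json(
        outdir / "divergence.json",
        {"mean_Ks": est.mean_Ks, "rate": est.rate, "time_years": est.time_years,
         "time_mya": est.time_years / 1e6, "n_pairs": int(finite.size)},
    )
    return ["divergence.json"]


def _stage_colinearity(params: dict, outdir: Path, artifacts: dict) -> list[str]:
    genes = pio.read_gff3_genes(params["genes_gff"])
    order = pio.read_pathway_order(params["order_tsv"])
    res = colinearity(
        genes,
        order,
        n_perm=int(params.get("n_perm", 9999)),
        seed=int(params.get("seed", 0)),
        telomere=params.get("telomere", "start"),
        chrom_length=params.get("chrom_length"),
    )
    _write_json(
        outdir / "colinearity.json",
        {"tau": res.tau, "p_perm": res.p_perm, "n_genes": res.n_genes,
         "orientation": res.orientation,
         "note": "tau statistic constructed here; the colinearity of "
                 "characterised clusters is reported qualitatively in the literature"},
    )
    return ["colinearity.json"]


_STAGES = {
    "simulate": _stage_simulate,
    "genome_size": _stage_genome_size,
    "density": _stage_density,
    "coexpr": _stage_coexpr,
    "dnds": _stage_dnds,
    "date": _stage_date,
    "colinearity": _stage_colinearity,
}


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _tuplify(d: dict) -> dict:
    """YAML lists -> tuples so dataclass configs hash/compare cleanly."""
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out
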