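"""End-to-end orchestration: QC -> LD -> Ne -> FST -> iHS -> genes ->
tree/PCA -> FecB, with per-stage artifacts and a collated summary.

Every stage writes a plain-text table (TSV/BED/Newick/PHYLIP) plus a JSON
sidecar of the parameters it ran with; the summary collates the decay
table, window counts, gene lists and FecB statistics.  All artifacts are
reproducible byte-for-byte from (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    candidate_genes,
    fecb_stats,
    fst_scan,
    genotype_io,
    ihs_scan,
    ld_decay,
    structure_diversity,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage inputs and parameters, with the study defaults."""

    vcf: str = ""
    popmap: str = ""
    gff: str | None = None
    litter_csv: str | None = None
    out_dir: str = "popscan_out"
    seed: int = 0
    # QC
    min_individual_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    hwe_p_min: float = 1e-6
    autosomes_only: bool = True
    # LD
    ld_bins: tuple = ld_decay.DEFAULT_BINS_BP
    ld_max_distance: int = 1_000_000
    ld_population: str | None = None  # default: first population in the popmap
    cm_per_mb: float = 1.0
    # FST
    fst_window: int = 50_000
    fst_step: int = 25_000
    fst_top_fraction: float = 0.05
    # iHS
    ihs_min_maf: float = 0.05
    ihs_cutoff: float = 0.05
    ihs_max_gap: int = 200_000
    ihs_top_fraction: float = 0.01
    ancestral_tag: str = "AA"
    skip_ihs: bool = False
    # structure
    pca_components: int = 2


def _restrict_to_dataset(haps, dataset):
    """Drop haplotype sites not retained (by chrom+pos) in the QC'd dataset."""
    wanted = set(zip(map(str, dataset.chrom), dataset.pos.tolist()))
    keep = np.array(
        [(str(c), int(p)) in wanted for c, p in zip(haps.chrom, haps.pos)]
    )
    return ihs_scan.HaplotypeSet(
        haplotypes=haps.haplotypes[:, keep], chrom=haps.chrom[keep], pos=haps.pos[keep]
    )


def _write_tsv(frame: pd.DataFrame, path: Path):
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sidecar(path: Path, params: dict):
    path.with_suffix(path.suffix + ".params.json").write_text(
        json.dumps(params, indent=2, default=str)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns {stage: artifact path}.

    A stage failure raises with the stage name in the message; artifacts
    of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- QC ---------------------------------------------------------
    name = stage("qc")
    try:
        dataset = genotype_io.read_vcf(config.vcf, config.popmap)
        params = genotype_io.QCParams(
            min_individual_call_rate=config.min_individual_call_rate,
            min_snp_call_rate=config.min_snp_call_rate,
            hwe_p_min=config.hwe_p_min,
            autosomes_only=config.autosomes_only,
        )
        dataset, report = genotype_io.apply_qc(dataset, params)
        qc_path = out / "qc_report.json"
        qc_path.write_text(json.dumps(report.to_dict(), indent=2))
        artifacts["qc"] = qc_path
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    pops = list(dict.fromkeys(dataset.populations))
    ld_pop = config.ld_population or pops[0]

    # ---- LD decay + Ne ---------------------------------------------
    name = stage("ld")
    try:
        ld_ds = dataset.subset_samples(dataset.population_index(ld_pop))
        # phased input bypasses EM: reuse the haplotype path when available
        if dataset.phased:
            haps = ihs_scan.read_phased_vcf(
                config.vcf, samples=ld_ds.sample_ids, aa_tag=config.ancestral_tag
            )
            haps = _restrict_to_dataset(haps, ld_ds)
            table = ld_decay.ld_decay_profile(
                haps, bins=config.ld_bins, max_distance=config.ld_max_distance
            )
        else:
            table = ld_decay.ld_decay_profile(
                ld_ds, bins=config.ld_bins, max_distance=config.ld_max_distance
            )
        ld_path = out / "ld_decay.tsv"
        _write_tsv(table.to_frame(), ld_path)
        _sidecar(ld_path, {"population": ld_pop, "max_distance": config.ld_max_distance})
        artifacts["ld"] = ld_path

        traj = ld_decay.ne_from_ld(table, n_samples=ld_ds.n_samples,
                                   cm_per_mb=config.cm_per_mb)
        ne_path = out / "ne_trajectory.tsv"
        _write_tsv(traj.to_frame(), ne_path)
        artifacts["ne"] = ne_path
        ld_table = table
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- FST --------------------------------------------------------
    name = stage("fst")
    try:
        if len(pops) < 2:
            raise ValueError("FST needs two populations")
        comp = fst_scan.components_from_dataset(dataset, pops[0], pops[1])
        track = fst_scan.windowed_fst(comp, window=config.fst_window,
                                      step=config.fst_step)
        fst_path = out / "fst_windows.tsv"
        _write_tsv(track.frame, fst_path)
        _sidecar(fst_path, {"window": config.fst_window, "step": config.fst_step})
        artifacts["fst"] = fst_path

        top_windows = fst_scan.select_top_windows(track, config.fst_top_fraction)
        bed = out / "fst_top_windows.bed"
        with open(bed, "w") as fh:
            for _, row in top_windows.iterrows():
                fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.fst:.6g}\n")
        artifacts["fst_top"] = bed
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- iHS --------------------------------------------------------
    top_snps = None
    if config.skip_ihs:
        logger.info("iHS stage skipped by config")
    elif not dataset.phased:
        logger.warning("input VCF is unphased; iHS stage skipped")
    else:
        name = stage("ihs")
        try:
            focal = dataset.subset_samples(dataset.population_index(ld_pop))
            haps = ihs_scan.read_phased_vcf(
                config.vcf, samples=focal.sample_ids, aa_tag=config.ancestral_tag
            )
            haps = _restrict_to_dataset(haps, focal)
            result = ihs_scan.scan_ihs(
                haps,
                min_maf=config.ihs_min_maf,
                cutoff=config.ihs_cutoff,
                max_gap=config.ihs_max_gap,
            )
            ihs_path = out / "ihs.tsv"
            _write_tsv(result.frame, ihs_path)
            _sidecar(ihs_path, {"population": ld_pop, "min_maf": config.ihs_min_maf})
            artifacts["ihs"] = ihs_path

            top_snps = ihs_scan.select_top_snps(result, config.ihs_top_fraction)
            bed = out / "ihs_top_snps.bed"
            with open(bed, "w") as fh:
                for _, row in top_snps.iterrows():
                    fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.ihs:.6g}\n")
            artifacts["ihs_top"] = bed
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- candidate genes -------------------------------------------
    genes_fst = genes_ihs = intersection = None
    if config.gff:
        name = stage("genes")
        try:
            models = candidate_genes.read_gene_models(config.gff)
            fst_regions = [
                (row.chrom, int(row.start), int(row.end))
                for _, row in top_windows.iterrows()
            ]
            genes_fst = candidate_genes.map_to_genes(fst_regions, models)
            (out / "genes_fst.txt").write_text("\n".join(sorted(genes_fst)) + "\n")
            artifacts["genes_fst"] = out / "genes_fst.txt"
            if top_snps is not None:
                snp_regions = [(row.chrom, int(row.pos)) for _, row in top_snps.iterrows()]
                genes_ihs = candidate_genes.map_to_genes(snp_regions, models)
                (out / "genes_ihs.txt").write_text("\n".join(sorted(genes_ihs)) + "\n")
                artifacts["genes_ihs"] = out / "genes_ihs.txt"
                intersection = candidate_genes.intersect_gene_sets(genes_fst, genes_ihs)
                mode = "fst_and_ihs"
            else:
                intersection = sorted(genes_fst)
                mode = "fst_only"
            (out / "genes_intersection.txt").write_text(
                f"# mode: {mode}\n" + "\n".join(intersection) + "\n"
            )
            artifacts["genes_intersection"] = out / "genes_intersection.txt"
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- structure: tree + PCA -------------------------------------
    name = stage("structure")
    try:
        dm = structure_diversity.p_distance_matrix(dataset)
        (out / "p_distance.phylip").write_text(dm.to_phylip())
        tree = structure_diversity.nj_tree(dm)
        (out / "nj_tree.nwk").write_text(tree.newick() + "\n")
        artifacts["tree"] = out / "nj_tree.nwk"

        coords, explained = structure_diversity.pca_genotypes(
            dataset, k=config.pca_components
        )
        pca_frame = pd.DataFrame(
            coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
        )
        pca_frame.insert(0, "sample", dataset.sample_ids)
        pca_frame.insert(1, "population", dataset.populations)
        pca_path = out / "pca.tsv"
        _write_tsv(pca_frame, pca_path)
        _sidecar(pca_path, {"explained_variance": explained.tolist()})
        artifacts["pca"] = pca_path
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- FecB -------------------------------------------------------
    fecb_summary = None
    if config.litter_csv:
        name = stage("fecb")
        try:
            records = fecb_stats.read_litter_csv(config.litter_csv)
            counts = {"BB": 0, "B+": 0, "++": 0}
            for r in records:
                counts[r.genotype] += 1
            table = fecb_stats.GenotypeCountTable(
                counts["BB"], counts["B+"], counts["++"]
            )
            freqs = fecb_stats.genotype_allele_freqs(table)
            chi2, p, in_hwe = fecb_stats.fecb_hwe(table)
            summary, pairwise = fecb_stats.litter_size_comparison(records)
            fecb_path = out / "fecb_summary.tsv"
            _write_tsv(summary, fecb_path)
            _sidecar(
                fecb_path,
                {
                    "genotype_freq": freqs["genotype_freq"],
                    "allele_freq": freqs["allele_freq"],
                    "hwe_chi2": chi2,
                    "hwe_p": p,
                    "in_hwe": bool(in_hwe),
                },
            )
            artifacts["fecb"] = fecb_path
            fecb_summary = {
                "counts": counts,
                **freqs,
                "hwe": {"chi2": chi2, "p": p, "in_hwe": bool(in_hwe)},
                "litter_means": summary.set_index("genotype")[
                    "mean_litter_size"
                ].to_dict(),
            }
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- summary ----------------------------------------------------
    summary = {
        "config": asdict(config),
        "qc": report.to_dict(),
        "ld_decay": ld_table.to_frame().to_dict(orient="records"),
        "n_fst_windows": int(len(track)),
        "n_top_fst_windows": int(len(top_windows)),
        "genes_fst": sorted(genes_fst) if genes_fst is not None else None,
        "genes_ihs": sorted(genes_ihs) if genes_ihs is not None else None,
        "genes_intersection": intersection,
        "fecb": fecb_summary,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str))
    artifacts["summary"] = summary_path
    return artifacts
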