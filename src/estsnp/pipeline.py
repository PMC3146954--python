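"""Workflow orchestration: simulate, discover, validate.

``run_discover`` chains trimming, assembly, SNP discovery and annotation and
writes every stage report plus a funnel manifest.  ``run_validate`` runs the
outlier scan first, then computes all downstream population statistics on
the neutral marker subset, mirroring the practice of validating a new panel
on strictly neutral loci.  ``run_simulate`` exposes the synthetic generators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as est_io
from .assemble import AssemblyConfig, assemble
from .annotate import annotate_marker, build_spectrum, predict_orf
from .popgen import (CalibrationError, GenotypeMatrix, locus_statistics,
                     mantel_ibd, mixture_clustering, outlier_scan, wc_fst)
from .preprocess import QualityRead, TrimConfig, assign_default_quality, trim_reads
from .snpdiscover import DiscoveryConfig, discover_snps
from .synthgen import (SMART_ADAPTER, OutlierSpec, PhredProfile,
                       generate_est_library, generate_island_genotypes)

__all__ = ["RunConfig", "run_simulate", "run_discover", "run_validate"]


@dataclass
class PopgenConfig:
    n_outlier_sim: int = 10_000
    outlier_bins: int = 20
    fst_permutations: int = 999
    mantel_permutations: int = 10_000
    cluster_k_min: int = 2
    cluster_k_max: int = 12
    cluster_restarts: int = 20
    run_bayes_scan: bool = False


@dataclass
class RunConfig:
    trim: TrimConfig = field(default_factory=lambda: TrimConfig(
        adapter_sequences=(SMART_ADAPTER,)))
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    popgen: PopgenConfig = field(default_factory=PopgenConfig)
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, target in (("trim", cfg.trim), ("assembly", cfg.assembly),
                                ("discovery", cfg.discovery), ("popgen", cfg.popgen)):
            for key, value in (raw.get(section) or {}).items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown {section} option {key!r}")
                if key == "adapter_sequences":
                    value = tuple(value)
                setattr(target, key, value)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.verbosity = int(raw.get("verbosity", cfg.verbosity))
        return cfg


def run_simulate(outdir: str, cfg: RunConfig | None = None, *,
                 n_genes: int = 200, reads_per_gene_mean: float = 8.0,
                 snp_rate: float = 0.002, error_profile: PhredProfile | None = None,
                 n_demes: int = 6, n_per_deme: int = 31, n_loci: int = 62,
                 f_neutral: float = 0.13,
                 outlier_spec: list[OutlierSpec] | None = None) -> dict:
    """Write a complete synthetic study (EST library + genotypes + truth)."""
    cfg = cfg or RunConfig()
    est_io.ensure_dir(outdir)
    reads, truth = generate_est_library(
        n_genes, reads_per_gene_mean, snp_rate, error_profile, seed=cfg.seed)
    est_io.write_fasta_qual(reads, f"{outdir}/reads.fasta", f"{outdir}/reads.qual")
    for name, frame in truth.to_frames().items():
        est_io.write_tsv(frame, f"{outdir}/truth_{name}.tsv")
    g, island_truth = generate_island_genotypes(
        n_demes, n_per_deme, n_loci, f_neutral, outlier_spec, seed=cfg.seed)
    g.to_tsv(f"{outdir}/genotypes.tsv", f"{outdir}/coords.tsv")
    est_io.write_tsv(island_truth.to_frame(), f"{outdir}/truth_island_loci.tsv")
    manifest = {"seed": cfg.seed, "n_reads": len(reads),
                "n_planted_snps": len(truth.planted_snps),
                "n_individuals": g.n_individuals, "n_loci": g.n_loci}
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_discover(reads: list[QualityRead] | str, outdir: str,
                 cfg: RunConfig | None = None,
                 qual_path: str | None = None) -> dict:
    """Discovery workflow: trim -> assemble -> detect/filter/select -> annotate.

    ``reads`` may be a FASTA path (with optional companion QUAL) or an
    in-memory read list.  Returns the funnel manifest.
    """
    cfg = cfg or RunConfig()
    est_io.ensure_dir(outdir)
    if isinstance(reads, str):
        reads = est_io.read_fasta_qual(reads, qual_path)
        if qual_path is None:
            reads = assign_default_quality(reads, cfg.trim.default_quality)

    trimmed, trim_report = trim_reads(reads, cfg.trim)
    est_io.write_fasta_qual(trimmed, f"{outdir}/trimmed.fasta", f"{outdir}/trimmed.qual")
    est_io.write_tsv(pd.DataFrame(
        sorted(trim_report.dispositions.items()), columns=["read_id", "disposition"]),
        f"{outdir}/dispositions.tsv")

    contigs, singlets = assemble(trimmed, cfg.assembly)
    est_io.write_fasta_qual(
        [QualityRead(c.contig_id, c.consensus, c.consensus_quals) for c in contigs],
        f"{outdir}/contigs.fasta")
    est_io.write_ace(contigs, f"{outdir}/contigs.ace")

    candidates, selected = discover_snps(contigs, cfg.discovery)
    est_io.write_tsv(pd.DataFrame(
        [(c.contig_id, c.column, c.major_allele, c.minor_allele, c.depth,
          c.minor_count, c.multiallelic, ",".join(sorted(c.votes)),
          ",".join(sorted(c.filter_flags)), c.selected)
         for c in candidates],
        columns=["contig", "column", "major", "minor", "depth", "minor_count",
                 "multiallelic", "votes", "filters", "selected"]),
        f"{outdir}/candidates.tsv")
    est_io.write_marker_vcf(selected, contigs, f"{outdir}/markers.vcf")

    by_contig = {c.contig_id: c for c in contigs}
    markers = []
    for cand in selected:
        contig = by_contig[cand.contig_id]
        orf = predict_orf(contig.consensus)
        grade = {c.column: (c.major_allele, c.minor_allele)
                 for c in candidates
                 if c.contig_id == cand.contig_id
                 and c.minor_count >= cfg.discovery.min_minor_count}
        markers.append(annotate_marker(
            contig.consensus, cand, orf, grade,
            cfg.discovery.flank_window, cfg.discovery.max_flank_polymorphisms))
    est_io.write_tsv(pd.DataFrame(
        [(m.contig_id, m.column + 1, m.candidate.major_allele,
          m.candidate.minor_allele, m.codon_position, m.substitution_class,
          "" if m.aa_change is None else f"{m.aa_change[0]}>{m.aa_change[1]}",
          m.tstv, m.flank_polymorphism_count, m.assay_risk, m.flank5, m.flank3)
         for m in markers],
        columns=["contig", "position_1based", "major", "minor", "codon_position",
                 "class", "aa_change", "tstv", "flank_polymorphisms",
                 "assay_risk", "flank5", "flank3"]),
        f"{outdir}/markers.tsv")
    est_io.write_tsv(build_spectrum(markers).to_frame(), f"{outdir}/spectrum.tsv")

    manifest = {
        "seed": cfg.seed,
        "n_raw_reads": len(reads),
        "n_trimmed_reads": len(trimmed),
        "n_contigs": len(contigs),
        "n_singlets": len(singlets),
        "n_deep_contigs": sum(len(c.rows) >= cfg.discovery.min_depth for c in contigs),
        "n_candidate_columns": len(candidates),
        "n_voted_candidates": sum(
            len(c.votes) >= cfg.discovery.min_votes for c in candidates),
        "n_selected_markers": len(selected),
    }
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_validate(genotypes: GenotypeMatrix | str, outdir: str,
                 cfg: RunConfig | None = None,
                 coords_path: str | None = None) -> dict:
    """Validation workflow on a genotype panel.

    Outlier scan first; F_ST, Mantel and mixture clustering then use only the
    loci the envelope calls neutral.  Degenerate inputs (too few polymorphic
    loci, identical coordinates) skip the affected stage with a warning
    recorded in the summary.
    """
    cfg = cfg or RunConfig()
    est_io.ensure_dir(outdir)
    if isinstance(genotypes, str):
        genotypes = GenotypeMatrix.from_tsv(genotypes, coords_path)
    g = genotypes
    if not g.coords.empty:
        unknown = set(g.coords["population"]) - set(g.populations)
        if unknown:
            raise ValueError(f"coordinates name unknown population(s): {sorted(unknown)}")
    summary: dict = {"seed": cfg.seed, "warnings": [],
                     "n_individuals": g.n_individuals, "n_loci": g.n_loci}

    est_io.write_tsv(locus_statistics(g), f"{outdir}/locus_stats.tsv")

    maf = np.array([
        min(p, 1 - p) if np.isfinite(p) else 0.0
        for p in (np.nansum(g.dosages, axis=0)
                  / np.maximum(2 * (~np.isnan(g.dosages)).sum(axis=0), 1))])
    n_poly = int((maf > 0).sum())
    neutral = g
    if n_poly < 2:
        summary["warnings"].append("outlier scan skipped: fewer than two "
                                   "polymorphic loci (cannot calibrate)")
    else:
        try:
            report = outlier_scan(g, n_sim=cfg.popgen.n_outlier_sim,
                                  n_bins=cfg.popgen.outlier_bins, seed=cfg.seed)
        except CalibrationError as exc:
            summary["warnings"].append(f"outlier scan skipped: {exc}")
        else:
            est_io.write_tsv(report.table, f"{outdir}/outliers.tsv")
            summary["f_sim"] = report.f_sim
            summary["n_outliers"] = int(
                (report.table.classification != "neutral").sum())
            neutral = g.subset_loci(
                [locus in set(report.neutral_loci) for locus in g.loci])
    summary["n_neutral_loci"] = neutral.n_loci

    fst = wc_fst(neutral, pairwise=True,
                 n_permutations=cfg.popgen.fst_permutations, seed=cfg.seed)
    summary["global_theta"] = fst.global_theta
    est_io.write_tsv(fst.per_locus.rename("theta").reset_index()
                     .rename(columns={"index": "locus"}), f"{outdir}/fst_loci.tsv")
    fst.pairwise.to_csv(f"{outdir}/fst_pairwise.tsv", sep="\t")
    fst.pairwise_p.to_csv(f"{outdir}/fst_pairwise_p.tsv", sep="\t")

    if g.coords.empty or len(g.population_names) < 3:
        summary["warnings"].append("Mantel skipped: needs coordinates and at "
                                   "least three populations")
    elif g.coords[["x_km", "y_km"]].std().sum() == 0:
        summary["warnings"].append("Mantel skipped: zero geographic variance")
    else:
        try:
            mantel = mantel_ibd(fst.pairwise, g.coords,
                                n_permutations=cfg.popgen.mantel_permutations,
                                seed=cfg.seed)
        except ValueError as exc:
            summary["warnings"].append(f"Mantel skipped: {exc}")
        else:
            summary["mantel_r"] = mantel.r
            summary["mantel_p"] = mantel.p_value

    k_max = min(cfg.popgen.cluster_k_max, g.n_individuals)
    assignment = mixture_clustering(
        neutral, range(cfg.popgen.cluster_k_min, k_max + 1),
        n_restarts=cfg.popgen.cluster_restarts, seed=cfg.seed)
    summary["selected_k"] = assignment.selected_k
    est_io.write_tsv(pd.DataFrame({
        "individual": g.individuals, "population": g.populations,
        "cluster": assignment.labels + 1}), f"{outdir}/clusters.tsv")

    if cfg.popgen.run_bayes_scan:
        from .popgen import bayes_outlier_scan
        bayes = bayes_outlier_scan(g, seed=cfg.seed)
        est_io.write_tsv(bayes.table, f"{outdir}/bayes_outliers.tsv")
        summary["bayes_reliable"] = bayes.reliable

    with open(f"{outdir}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
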