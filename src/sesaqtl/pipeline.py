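"""Configuration-driven orchestration of the full analysis.

Stages run in order: genotype coding -> bin-map construction -> linkage
map -> phenotype summary -> QTL scans per trait -> interval consolidation
-> candidate-gene screen. Every stage writes plain-text outputs so any
stage can be re-run standalone, and a manifest records parameters, the
seed, and per-stage record counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binning, candidates, coding, genmap, intervals, phenostats
from .qtlscan import QTLScanModel, qtls_to_dataframe

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name and record context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All file paths and numeric parameters of the pipeline.

    The numeric defaults are the analysis settings of the study design
    this pipeline implements: 100 bp redundant-marker gap, 15-marker
    correction window, segregation filter at 20 homozygotes / 40
    heterozygotes, linkage LOD 12 with a 100-marker minimum group, 1 cM
    IM walk, 2 cM CIM walk with a 10 cM window, 1,000 permutations at
    alpha 0.05, 5 cM gap reporting, 2 cM hotspot-cluster gap, and DEG
    cutoffs padj < 0.05 with |log2FC| > 1 against the 5 DAF control.
    """

    vcf: str = ""
    phenotype: str = ""
    gff3: str = ""
    deg_table: str = ""
    variant_table: str = ""
    outdir: str = "results"
    parent1: str = "P1_white"
    parent2: str = "P2_black"
    black_col: str = "black"
    white_col: str = "white"
    reference_col: str = "reference"
    min_gap_bp: int = 100
    window: int = 15
    min_hom: int = 20
    min_het: int = 40
    lod_threshold: float = 12.0
    min_group_size: int = 100
    method: str = "im"
    im_step: float = 1.0
    cim_step: float = 2.0
    cim_window: float = 10.0
    max_cofactors: int = 5
    n_perm: int = 1000
    alpha: float = 0.05
    gap_threshold: float = 5.0
    cluster_max_gap: float = 2.0
    padj_cut: float = 0.05
    lfc_cut: float = 1.0
    control_stage: int = 5
    late_stages: list[int] = field(default_factory=lambda: [10, 15, 20, 25])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _require(path: str, stage: str, what: str) -> Path:
    p = Path(path)
    if not path or not p.exists():
        raise PipelineError(stage, f"{what} not readable: {path!r}")
    return p


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to
    ``outdir/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}}
    rng = np.random.default_rng(config.seed)

    # Preflight: every stage's inputs must be readable before work starts.
    _require(config.vcf, "coding", "VCF")
    pheno_path = _require(config.phenotype, "phenostats/qtlscan",
                          "phenotype table")

    # ----- coding -------------------------------------------------------
    sites = coding.read_vcf(config.vcf, config.parent1, config.parent2)
    informative = coding.select_informative_sites(sites)
    if not informative:
        raise PipelineError("coding", "no informative sites in VCF")
    progeny = coding.progeny_names_from_vcf(config.vcf, config.parent1,
                                            config.parent2)
    matrix = coding.code_genotypes(informative, progeny)
    matrix.to_tsv(out / "coded_matrix.tsv")
    manifest["stages"]["coding"] = {
        "sites_in": len(sites), "informative": len(informative),
        "individuals": matrix.n_individuals}

    # ----- binning ------------------------------------------------------
    reps = binning.collapse_redundant(matrix, min_gap_bp=config.min_gap_bp)
    reps, audit = binning.window_correct(reps, window=config.window,
                                         return_audit=True)
    audit.to_csv(out / "correction_audit.tsv", sep="\t", index=False)
    raw_bins = binning.build_bins(reps)
    bins = binning.filter_distorted(raw_bins, min_hom=config.min_hom,
                                    min_het=config.min_het)
    if not bins:
        raise PipelineError("binning", "all bins removed by the "
                            "segregation-distortion filter")
    binning.write_bins_tsv(bins, out / "bins.tsv")
    manifest["stages"]["binning"] = {
        "markers_in": matrix.n_markers, "representatives": len(reps),
        "corrections": len(audit), "bins": len(raw_bins),
        "bins_kept": len(bins)}

    # ----- genetic map --------------------------------------------------
    contig_order = list(dict.fromkeys(matrix.markers["contig"]))
    gmap = genmap.group_bins(bins, lod_threshold=config.lod_threshold,
                             min_group_size=config.min_group_size,
                             contig_order=contig_order)
    if not gmap.groups:
        raise PipelineError("genmap", "no linkage group survived the "
                            "minimum-marker filter")
    genmap.space_map(gmap)
    genmap.write_map_tsv(gmap, out / "genetic_map.tsv")
    stats = genmap.map_stats(gmap, gap_threshold=config.gap_threshold)
    stats.summary_frame().to_csv(out / "map_stats.tsv", sep="\t",
                                 index=False)
    manifest["stages"]["genmap"] = {
        "groups": len(gmap.groups), "total_length_cM":
        round(stats.total_length_cM, 2), "bins": stats.total_bins,
        "markers": stats.total_markers}

    # ----- phenotype summary -------------------------------------------
    pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)
    summary = phenostats.summarize_phenotypes(pheno)
    phenostats.write_summary(summary, out / "phenotype_summary.tsv",
                             out / "phenotype_correlations.csv")
    manifest["stages"]["phenostats"] = {"individuals": len(pheno),
                                        "traits": list(pheno.columns)}

    # ----- QTL scans ----------------------------------------------------
    all_calls = []
    scan_frames = []
    thresholds = {}
    step = config.im_step if config.method == "im" else config.cim_step
    for trait in pheno.columns:
        model = QTLScanModel(gmap, pheno, str(trait), method=config.method,
                             step=step, cim_window=config.cim_window,
                             max_cofactors=config.max_cofactors,
                             individuals=matrix.individuals)
        res = model.fit(n_perm=config.n_perm, alpha=config.alpha,
                        seed=int(rng.integers(2 ** 31)))
        thresholds[str(trait)] = res.threshold
        frame = res.scan.profile.copy()
        frame.insert(0, "trait", str(trait))
        frame["method"] = res.scan.method
        scan_frames.append(frame)
        all_calls.extend(res.qtls)
    pd.concat(scan_frames).to_csv(out / "scans.tsv", sep="\t", index=False)
    with open(out / "thresholds.json", "w") as fh:
        json.dump(thresholds, fh, indent=2)
    qtl_frame = qtls_to_dataframe(all_calls)
    qtl_frame.to_csv(out / "qtl_table.tsv", sep="\t", index=False)
    manifest["stages"]["qtlscan"] = {
        "traits": len(thresholds), "qtls": len(all_calls),
        "thresholds": {k: round(v, 3) for k, v in thresholds.items()}}

    # ----- interval consolidation --------------------------------------
    merged = intervals.merge_overlapping(all_calls) if all_calls else []
    clustered = intervals.cluster_adjacent(merged,
                                           max_gap=config.cluster_max_gap)
    intervals.write_intervals_tsv(merged, out / "qtl_intervals.tsv")
    intervals.write_intervals_tsv(clustered, out / "qsc_intervals.tsv")
    segments = []
    for iv in clustered:
        segments.extend(intervals.to_physical(iv, gmap))
    intervals.write_segments_bed(segments, out / "qsc_segments.bed")
    manifest["stages"]["intervals"] = {
        "qtls_in": len(all_calls), "merged": len(merged),
        "clustered": len(clustered), "segments": len(segments)}

    # ----- candidate screen --------------------------------------------
    if config.gff3 and config.variant_table and config.deg_table:
        genes = candidates.read_gff3(_require(config.gff3, "candidates",
                                              "GFF3"))
        in_seg = candidates.genes_in_segments(genes, segments)
        variants = pd.read_csv(_require(config.variant_table, "candidates",
                                        "variant table"), sep="\t")
        coseg = candidates.coseg_screen(variants, config.black_col,
                                        config.white_col,
                                        config.reference_col)
        if "impact" in coseg.columns:
            high = coseg[coseg["impact"].str.lower() == "high"]
        elif "ann" in coseg.columns:
            rows = []
            for _, r in coseg.iterrows():
                for eff in candidates.parse_ann(r["ann"], r.get("contig", ""),
                                                int(r.get("position", 0))):
                    if eff.impact == "high":
                        rows.append({**r.to_dict(), "gene_id": eff.gene_id})
            high = pd.DataFrame(rows, columns=list(coseg.columns))
        else:
            raise PipelineError("candidates", "variant table needs an "
                                "'impact' or 'ann' column")
        seg_ids = {g.gene_id for g in in_seg}
        high = high[high["gene_id"].isin(seg_ids)]
        deg = pd.read_csv(_require(config.deg_table, "candidates",
                                   "DEG table"), sep="\t")
        flags = candidates.deg_flags(deg, config.padj_cut, config.lfc_cut)
        evidence = candidates.screen_candidates(
            in_seg, high, flags, late_stages=tuple(config.late_stages),
            control_stage=config.control_stage)
        candidates.evidence_to_dataframe(evidence).to_csv(
            out / "candidate_evidence.tsv", sep="\t", index=False)
        venn = candidates.venn_summary(evidence)
        with open(out / "venn_summary.json", "w") as fh:
            json.dump(venn, fh, indent=2)
        manifest["stages"]["candidates"] = {
            "genes_total": len(genes), "genes_in_segments": len(in_seg),
            "coseg_variants": len(coseg), "coseg_high": len(high),
            **venn}
    else:
        manifest["stages"]["candidates"] = {"skipped": "no annotation inputs"}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
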