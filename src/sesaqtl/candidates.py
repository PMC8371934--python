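"""Candidate-gene screening inside consolidated QTL intervals.

A gene is a candidate for the trait when three independent lines of
evidence agree:

1. it lies in a QTL physical segment (>= 1 bp overlap);
2. it carries at least one high-impact variant whose allele configuration
   co-segregates with the trait contrast — homozygous-alternate in the
   black-seeded parent and homozygous-reference in both white lines;
3. it is differentially expressed in developing seeds at one or more of
   the late stages (10/15/20/25 days after flowering) but not at the
   5 DAF control, at FDR-adjusted p < 0.05 and |log2 fold change| > 1.

Variant impact can come from pre-annotated SnpEff-style ANN strings or
from the built-in minimal effect caller, which covers the high-impact
classes (frameshift, stop gained/lost, start lost, splice acceptor/donor,
exon loss) plus synonymous/missense; regulatory and UTR classes are
deliberately out of scope and fall through as modifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .intervals import PhysicalSegment

logger = logging.getLogger(__name__)

HIGH_IMPACT_EFFECTS = {
    "frameshift_variant", "stop_gained", "stop_lost", "start_lost",
    "splice_acceptor_variant", "splice_donor_variant", "exon_loss_variant",
}

LATE_STAGES = (10, 15, 20, 25)
CONTROL_STAGE = 5


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds_parts: list[tuple[int, int]] = field(default_factory=list)
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for s, e in self.cds_parts:
            if s < self.start or e > self.end:
                raise ValueError("CDS part outside gene span")


@dataclass
class VariantEffect:
    contig: str
    position: int
    ref: str
    alt: str
    gene_id: str
    effect: str
    impact: str  # high / moderate / low / modifier


@dataclass
class CandidateEvidence:
    gene_id: str
    n_coseg_high_impact_variants: int
    deg_stages: list[int]
    deg_at_control: bool
    passes: bool


# ----------------------------------------------------------------- GFF3

def read_gff3(path) -> list[GeneModel]:
    """Gene models (with phased CDS parts) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        cds = sorted((c.start, c.end) for c in
                     db.children(g, featuretype="CDS"))
        ann = g.attributes.get("Name", [g.id])[0]
        genes.append(GeneModel(g.id, g.seqid, g.start, g.end, g.strand,
                               cds, ann))
    return genes


# ----------------------------------------------------- interval gene sets

def genes_in_segments(genes: Iterable[GeneModel],
                      segments: Sequence[PhysicalSegment]) -> list[GeneModel]:
    """Genes whose span overlaps any segment by >= 1 bp, deduplicated.
    Genes on contigs absent from all segments are skipped silently."""
    by_contig: dict[str, list[PhysicalSegment]] = {}
    for seg in segments:
        by_contig.setdefault(seg.contig, []).append(seg)
    seen: set[str] = set()
    out: list[GeneModel] = []
    for g in genes:
        if g.gene_id in seen:
            continue
        for seg in by_contig.get(g.contig, ()):
            if g.start <= seg.end_bp and g.end >= seg.start_bp:
                out.append(g)
                seen.add(g.gene_id)
                break
    return out


# ------------------------------------------------------ co-segregation

def _alleles(gt: str) -> set[str] | None:
    if not isinstance(gt, str) or "." in gt:
        return None
    for sep in ("/", "|"):
        if sep in gt:
            return set(gt.split(sep))
    return set(gt)


def coseg_screen(variants: pd.DataFrame, black_col: str = "black",
                 white_col: str = "white",
                 reference_col: str = "reference") -> pd.DataFrame:
    """Keep variants homozygous-alternate in the black parent and
    homozygous-reference in both white lines; missing genotypes in any of
    the three lines remove the variant (conservative)."""
    def keep(row) -> bool:
        b = _alleles(row[black_col])
        w = _alleles(row[white_col])
        r = _alleles(row[reference_col])
        if b is None or w is None or r is None:
            return False
        return (len(b) == 1 and "0" not in b
                and w == {"0"} and r == {"0"})

    mask = variants.apply(keep, axis=1)
    return variants.loc[mask].reset_index(drop=True)


# ----------------------------------------------------- impact classification

def parse_ann(ann_field: str, contig: str = "", position: int = 0,
              ref: str = "", alt: str = "") -> list[VariantEffect]:
    """Parse a SnpEff-style ANN INFO field into per-gene effects.

    Field layout: ``Allele|Annotation|Impact|Gene_Name|Gene_ID|...``; only
    the first five sub-fields are consumed.
    """
    out = []
    for entry in ann_field.split(","):
        parts = entry.split("|")
        if len(parts) < 5:
            continue
        out.append(VariantEffect(contig, position, ref, alt,
                                 gene_id=parts[4] or parts[3],
                                 effect=parts[1],
                                 impact=parts[2].lower()))
    return out


def _cds_index(gene: GeneModel, pos: int) -> int | None:
    """0-based index of a genomic position within the spliced CDS, in
    coding orientation; None when the position is not coding."""
    parts = gene.cds_parts
    if gene.strand == "+":
        off = 0
        for s, e in parts:
            if s <= pos <= e:
                return off + (pos - s)
            off += e - s + 1
    else:
        off = 0
        for s, e in reversed(parts):
            if s <= pos <= e:
                return off + (e - pos)
            off += e - s + 1
    return None


def _near_splice(gene: GeneModel, pos: int) -> str | None:
    """splice_donor / splice_acceptor when ``pos`` is within the first or
    last 2 bp of an intron between CDS parts."""
    parts = gene.cds_parts
    for (s1, e1), (s2, _e2) in zip(parts, parts[1:]):
        intron = (e1 + 1, s2 - 1)
        if intron[0] > intron[1]:
            continue
        at_left = intron[0] <= pos <= min(intron[0] + 1, intron[1])
        at_right = max(intron[1] - 1, intron[0]) <= pos <= intron[1]
        if at_left:
            return ("splice_donor_variant" if gene.strand == "+"
                    else "splice_acceptor_variant")
        if at_right:
            return ("splice_acceptor_variant" if gene.strand == "+"
                    else "splice_donor_variant")
    return None


_IMPACT_OF = {
    "frameshift_variant": "high", "stop_gained": "high", "stop_lost": "high",
    "start_lost": "high", "splice_acceptor_variant": "high",
    "splice_donor_variant": "high", "exon_loss_variant": "high",
    "missense_variant": "moderate", "inframe_indel": "moderate",
    "synonymous_variant": "low",
    "intron_variant": "modifier", "intergenic_variant": "modifier",
    "gene_variant": "modifier",
}


def classify_impact(contig: str, position: int, ref: str, alt: str,
                    gene: GeneModel, coding_sequence: str) -> VariantEffect:
    """Minimal built-in effect caller for one variant against one gene.

    ``coding_sequence`` is the spliced CDS in coding orientation (what the
    concatenated CDS parts read on the coding strand). Classification
    order: exon loss > splice site > frameshift/inframe indel > start
    loss > stop gain/loss > missense/synonymous; anything non-coding
    inside the gene is a modifier, as is anything outside it.
    """
    def make(effect: str) -> VariantEffect:
        return VariantEffect(contig, position, ref, alt, gene.gene_id,
                             effect, _IMPACT_OF[effect])

    var_end = position + len(ref) - 1
    if contig != gene.contig or var_end < gene.start or position > gene.end:
        return make("intergenic_variant")
    cds = coding_sequence.upper()
    if len(cds) % 3 != 0:
        logger.warning("CDS length of %s is not a multiple of 3",
                       gene.gene_id)
    # Whole-exon deletion.
    if len(ref) > len(alt):
        for s, e in gene.cds_parts:
            if position <= s and var_end >= e:
                return make("exon_loss_variant")
    splice = _near_splice(gene, position)
    if splice is None and var_end != position:
        splice = _near_splice(gene, var_end)
    in_cds = any(position <= e and var_end >= s for s, e in gene.cds_parts)
    if splice is not None and not in_cds:
        return make(splice)
    if not in_cds:
        return make("intron_variant" if gene.cds_parts else "gene_variant")
    if len(ref) != len(alt):
        if abs(len(ref) - len(alt)) % 3 != 0:
            return make("frameshift_variant")
        return make("inframe_indel")
    # SNV (or MNV treated base-by-base at its first coding base).
    idx = _cds_index(gene, position)
    if idx is None:
        return make(splice or "intron_variant")
    base = ref[0].upper()
    new = alt[0].upper()
    if gene.strand == "-":
        base = str(Seq(base).reverse_complement())
        new = str(Seq(new).reverse_complement())
    codon_i = idx // 3
    within = idx % 3
    codon = cds[3 * codon_i: 3 * codon_i + 3]
    if len(codon) < 3:
        return make("gene_variant")
    new_codon = codon[:within] + new + codon[within + 1:]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if codon_i == 0 and codon == "ATG" and new_codon != "ATG":
        return make("start_lost")
    if new_aa == "*" and old_aa != "*":
        return make("stop_gained")
    if old_aa == "*" and new_aa != "*":
        return make("stop_lost")
    if new_aa == old_aa:
        return make("synonymous_variant")
    return make("missense_variant")


# ------------------------------------------------------------- DEG logic

def deg_flags(records: pd.DataFrame, padj_cut: float = 0.05,
              lfc_cut: float = 1.0) -> pd.DataFrame:
    """Per-gene, per-stage DEG booleans: padj < cut AND |log2fc| > cut.
    A missing gene-stage record means not differentially expressed;
    duplicate records raise."""
    dup = records.duplicated(subset=["gene_id", "stage"])
    if dup.any():
        raise ValueError("duplicate gene-stage DEG records")
    rec = records.copy()
    rec["flag"] = (rec["padj"] < padj_cut) & (rec["log2fc"].abs() > lfc_cut)
    table = rec.pivot(index="gene_id", columns="stage", values="flag")
    return table.eq(True)  # NaN (missing stage) -> not DEG


# ---------------------------------------------------------------- screen

def screen_candidates(genes: Iterable[GeneModel | str],
                      coseg_high_variants: pd.DataFrame,
                      flags: pd.DataFrame,
                      late_stages: Sequence[int] = LATE_STAGES,
                      control_stage: int = CONTROL_STAGE
                      ) -> list[CandidateEvidence]:
    """Combine the three evidence lines for every gene in the QTL segments.

    ``coseg_high_variants`` must already be restricted to co-segregating,
    high-impact variants and carry a ``gene_id`` column. Evidence is
    recorded for non-passing genes too.
    """
    n_by_gene = (coseg_high_variants.groupby("gene_id").size()
                 if len(coseg_high_variants) else pd.Series(dtype=int))
    out: list[CandidateEvidence] = []
    for g in genes:
        gid = g.gene_id if isinstance(g, GeneModel) else str(g)
        n_var = int(n_by_gene.get(gid, 0))
        if gid in flags.index:
            row = flags.loc[gid]
            stages = [s for s in late_stages
                      if s in row.index and bool(row[s])]
            at_control = bool(row.get(control_stage, False))
        else:
            stages, at_control = [], False
        passes = n_var >= 1 and len(stages) >= 1 and not at_control
        out.append(CandidateEvidence(gid, n_var, stages, at_control, passes))
    return out


def venn_summary(evidence: Sequence[CandidateEvidence]) -> dict[str, int]:
    """Counts of the two evidence sets and their intersection: genes that
    pass the DEG filter (late-stage DEG, not at control), genes with >= 1
    co-segregating high-impact variant, and the candidates."""
    deg_ok = {e.gene_id for e in evidence
              if e.deg_stages and not e.deg_at_control}
    var_ok = {e.gene_id for e in evidence
              if e.n_coseg_high_impact_variants >= 1}
    return {
        "n_genes": len(evidence),
        "n_deg_filtered": len(deg_ok),
        "n_high_impact": len(var_ok),
        "n_candidates": len(deg_ok & var_ok),
        "n_deg_only": len(deg_ok - var_ok),
        "n_high_impact_only": len(var_ok - deg_ok),
    }


def evidence_to_dataframe(evidence: Sequence[CandidateEvidence]
                          ) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": e.gene_id,
        "n_coseg_high_impact_variants": e.n_coseg_high_impact_variants,
        "deg_stages": ",".join(str(s) for s in e.deg_stages),
        "deg_at_control": e.deg_at_control,
        "passes": e.passes} for e in evidence])
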