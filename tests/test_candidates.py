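"""Candidate screening: segment gene sets, co-segregation, variant impact
classification and the stage-wise DEG logic."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from sesaqtl.candidates import (GeneModel, classify_impact, coseg_screen,
                                deg_flags, genes_in_segments, parse_ann,
                                read_gff3, screen_candidates, venn_summary)
from sesaqtl.intervals import PhysicalSegment


def gene(start=1000, end=1999, strand="+", cds=None, contig="C1",
         gene_id="G1"):
    if cds is None:
        cds = [(start, end)]
    return GeneModel(gene_id, contig, start, end, strand, cds)


# -------------------------------------------------------------- segments

@pytest.mark.parametrize("gstart,gend,included", [
    (1200, 1800, True),    # fully inside
    (900, 1000, True),     # 1 bp boundary overlap
    (100, 999, False),     # just outside
    (2001, 2500, False),
])
def test_segment_overlap_rule(gstart, gend, included):
    seg = [PhysicalSegment("C1", 1000, 2000)]
    got = genes_in_segments([gene(gstart, gend)], seg)
    assert (len(got) == 1) == included


def test_gene_on_uncovered_contig_skipped():
    seg = [PhysicalSegment("C1", 1, 10_000)]
    assert genes_in_segments([gene(contig="C9")], seg) == []


def test_duplicate_genes_deduplicated():
    segs = [PhysicalSegment("C1", 1, 5000), PhysicalSegment("C1", 900, 6000)]
    assert len(genes_in_segments([gene()], segs)) == 1


# --------------------------------------------------------- co-segregation

def vtable(rows):
    return pd.DataFrame(rows, columns=["gene_id", "black", "white",
                                       "reference"])


@pytest.mark.parametrize("black,white,ref,kept", [
    ("1/1", "0/0", "0/0", True),
    ("1|1", "0/0", "0/0", True),     # phased separator accepted
    ("1/1", "1/1", "0/0", False),    # alt shared with a white line
    ("0/1", "0/0", "0/0", False),    # het black parent
    ("0/0", "0/0", "0/0", False),
    ("1/1", "./.", "0/0", False),    # missing white removed, conservative
])
def test_coseg_rules(black, white, ref, kept):
    out = coseg_screen(vtable([("G1", black, white, ref)]))
    assert (len(out) == 1) == kept


def test_coseg_ignores_progeny_columns():
    df = vtable([("G1", "1/1", "0/0", "0/0")])
    df["F2_001"] = "0/1"
    df2 = df.copy()
    df2["F2_001"] = "1/1"
    assert coseg_screen(df).equals(coseg_screen(df2).assign(F2_001="0/1")) \
        or len(coseg_screen(df)) == len(coseg_screen(df2)) == 1


# ------------------------------------------------------------ impact

def cds_gene(seq_len=30, strand="+"):
    # single-exon CDS at 1001..1000+len
    return gene(1001, 1000 + seq_len, strand,
                cds=[(1001, 1000 + seq_len)])


def test_frameshift_from_two_bp_deletion():
    g = cds_gene()
    eff = classify_impact("C1", 1010, "ACT", "A", g, "ATG" + "GCT" * 9)
    assert eff.effect == "frameshift_variant" and eff.impact == "high"


def test_inframe_deletion_is_moderate():
    g = cds_gene()
    eff = classify_impact("C1", 1010, "ACTG", "A", g, "ATG" + "GCT" * 9)
    assert eff.effect == "inframe_indel" and eff.impact == "moderate"


def test_stop_gained_tgg_to_tga():
    cds = "ATG" + "TGG" + "GCT" * 8  # codon 2 = TGG (Trp)
    g = cds_gene()
    # third base of codon 2 is CDS index 5 -> genomic 1006
    eff = classify_impact("C1", 1006, "G", "A", g, cds)
    assert eff.effect == "stop_gained" and eff.impact == "high"


def test_synonymous_is_low():
    cds = "ATG" + "CTG" + "GCT" * 8  # CTG->CTA both Leu
    eff = classify_impact("C1", 1006, "G", "A", cds_gene(), cds)
    assert eff.effect == "synonymous_variant" and eff.impact == "low"


def test_start_lost():
    cds = "ATG" + "GCT" * 9
    eff = classify_impact("C1", 1001, "A", "G", cds_gene(), cds)
    assert eff.effect == "start_lost" and eff.impact == "high"


def test_stop_lost():
    cds = "ATG" + "GCT" * 8 + "TAA"
    g = cds_gene()
    eff = classify_impact("C1", 1028, "A", "C", g, cds)  # TAA -> TCA
    assert eff.effect == "stop_lost" and eff.impact == "high"


def test_splice_sites_flagged():
    g = gene(1001, 2000, "+", cds=[(1001, 1200), (1501, 2000)])
    donor = classify_impact("C1", 1201, "G", "A", g, "ATG" + "GCT" * 100)
    acceptor = classify_impact("C1", 1500, "G", "A", g, "ATG" + "GCT" * 100)
    deep = classify_impact("C1", 1350, "G", "A", g, "ATG" + "GCT" * 100)
    assert donor.effect == "splice_donor_variant" and donor.impact == "high"
    assert acceptor.effect == "splice_acceptor_variant"
    assert deep.impact == "modifier"


def test_whole_exon_deletion():
    g = gene(1001, 2000, "+", cds=[(1001, 1200), (1501, 2000)])
    ref = "N" * 320
    eff = classify_impact("C1", 990, ref, "N", g, "ATG" + "GCT" * 100)
    assert eff.effect == "exon_loss_variant" and eff.impact == "high"


def test_intergenic_is_modifier():
    eff = classify_impact("C1", 50, "A", "G", cds_gene(), "ATG" + "GCT" * 9)
    assert eff.impact == "modifier"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_snv_classification_matches_codon_oracle(strand):
    """Every possible single-base substitution in a random CDS agrees
    with a brute-force translate-and-compare oracle."""
    rng = np.random.default_rng(42 if strand == "+" else 43)
    n_codons = 12
    body = "".join(rng.choice(list("ACGT"), size=3 * (n_codons - 2)))
    cds = "ATG" + body + "TAA"
    g = cds_gene(seq_len=len(cds), strand=strand)
    for cds_idx in range(len(cds)):
        if strand == "+":
            pos = 1001 + cds_idx
            ref_base = cds[cds_idx]
        else:
            pos = g.end - cds_idx
            ref_base = str(Seq(cds[cds_idx]).complement())
        for alt_base in "ACGT":
            if alt_base == ref_base:
                continue
            got = classify_impact("C1", pos, ref_base, alt_base, g, cds)
            # oracle: mutate the CDS directly and compare translations
            coding_alt = (alt_base if strand == "+"
                          else str(Seq(alt_base).complement()))
            mutated = cds[:cds_idx] + coding_alt + cds[cds_idx + 1:]
            old_aa = str(Seq(cds).translate())
            new_aa = str(Seq(mutated).translate())
            ci = cds_idx // 3
            if ci == 0 and mutated[:3] != "ATG":
                want = "start_lost"
            elif new_aa[ci] == "*" and old_aa[ci] != "*":
                want = "stop_gained"
            elif old_aa[ci] == "*" and new_aa[ci] != "*":
                want = "stop_lost"
            elif new_aa[ci] == old_aa[ci]:
                want = "synonymous_variant"
            else:
                want = "missense_variant"
            assert got.effect == want, (strand, cds_idx, ref_base, alt_base)


def test_parse_ann_field():
    ann = ("T|stop_gained|HIGH|PPO|G0042|transcript|G0042.t1|"
           "protein_coding|1/2|c.100C>T|p.Gln34*,"
           "T|upstream_gene_variant|MODIFIER|X|G0043|transcript|t|p|||")
    effs = parse_ann(ann, "C1", 123, "C", "T")
    assert [(e.gene_id, e.effect, e.impact) for e in effs] == [
        ("G0042", "stop_gained", "high"),
        ("G0043", "upstream_gene_variant", "modifier")]


# ---------------------------------------------------------------- DEG

@pytest.mark.parametrize("padj,lfc,flag", [
    (0.04, 1.2, True),
    (0.04, 0.8, False),   # fails fold change
    (0.06, 3.0, False),   # fails FDR
    (0.04, -1.2, True),   # absolute fold change
])
def test_deg_cutoffs(padj, lfc, flag):
    rec = pd.DataFrame([{"gene_id": "G1", "stage": 15, "log2fc": lfc,
                         "padj": padj}])
    assert bool(deg_flags(rec).loc["G1", 15]) == flag


def test_duplicate_deg_records_rejected():
    rec = pd.DataFrame([
        {"gene_id": "G1", "stage": 15, "log2fc": 2.0, "padj": 0.01},
        {"gene_id": "G1", "stage": 15, "log2fc": 1.5, "padj": 0.02}])
    with pytest.raises(ValueError, match="duplicate"):
        deg_flags(rec)


# --------------------------------------------------------------- screen

def make_flags(rows):
    return deg_flags(pd.DataFrame(rows, columns=["gene_id", "stage",
                                                 "log2fc", "padj"]))


def variants_for(*gene_ids):
    return pd.DataFrame({"gene_id": list(gene_ids)})


def test_screen_pass_and_fail_cases():
    flags = make_flags([("G1", 15, 2.0, 0.01),
                        ("G2", 5, 2.0, 0.01), ("G2", 15, 2.0, 0.01),
                        ("G3", 15, 2.0, 0.01)])
    ev = screen_candidates(["G1", "G2", "G3", "G4"],
                           variants_for("G1", "G2", "G4"), flags)
    result = {e.gene_id: e.passes for e in ev}
    assert result == {"G1": True,    # variant + late DEG, clean control
                      "G2": False,   # DEG at the 5 DAF control
                      "G3": False,   # no qualifying variant
                      "G4": False}   # no DEG evidence


def test_screen_monotone_in_conditions():
    """Dropping a filter condition never shrinks the passing set."""
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(30)]
    var_genes = list(rng.choice(genes, size=12, replace=False))
    rows = []
    for g in genes:
        for stage in (5, 10, 15, 20, 25):
            rows.append((g, stage, float(rng.normal(0, 2)),
                         float(rng.uniform(0, 0.2))))
    flags = make_flags(rows)
    full = {e.gene_id for e in
            screen_candidates(genes, variants_for(*var_genes), flags)
            if e.passes}
    no_var = {e.gene_id for e in
              screen_candidates(genes, variants_for(*genes), flags)
              if e.passes}
    no_control = {e.gene_id for e in
                  screen_candidates(genes, variants_for(*var_genes),
                                    flags, control_stage=99)
                  if e.passes}
    assert full <= no_var and full <= no_control


def test_venn_summary_counts():
    flags = make_flags([("G1", 15, 2.0, 0.01), ("G2", 15, 2.0, 0.01)])
    ev = screen_candidates(["G1", "G2", "G3"], variants_for("G1", "G3"),
                           flags)
    v = venn_summary(ev)
    assert v == {"n_genes": 3, "n_deg_filtered": 2, "n_high_impact": 2,
                 "n_candidates": 1, "n_deg_only": 1,
                 "n_high_impact_only": 1}


def test_gff3_round_trip(tmp_path):
    from sesaqtl.simdata import SimConfig, simulate_annotation, write_gff3

    genes, _, _ = simulate_annotation(SimConfig(seed=1), n_genes=10,
                                      n_planted_candidates=2, n_decoys=2)
    path = tmp_path / "genes.gff3"
    write_gff3(genes, path)
    back = read_gff3(path)
    assert len(back) == 10
    by_id = {g.gene_id: g for g in back}
    for g in genes:
        got = by_id[g.gene_id]
        assert (got.contig, got.start, got.end, got.strand) == \
            (g.contig, g.start, g.end, g.strand)
        assert got.cds_parts == g.exons
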