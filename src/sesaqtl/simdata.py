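"""Synthetic F2 intercross data with the error structure of low-coverage
resequencing.

The generator emulates a seed-coat-color mapping population: two inbred
parents fixed for opposite alleles at every marker, 120 F2 individuals on
13 chromosomes, colorimeter L/a/b phenotypes driven by a handful of QTLs,
and the characteristic low-coverage artifact in which short runs of true
heterozygotes are miscalled as one homozygote. It also plants candidate
genes (high-impact, trait-co-segregating variants plus a late-stage
differential-expression signature) among decoy genes, so the downstream
variant x transcriptome screen can be tested against a known answer.

Meiosis model: per gamete, the crossover count on a chromosome of length
``L`` cM is Poisson(L/100) with uniform positions and no interference, so
map distances are additive in expectation and the Kosambi function is a
short-range approximation to the induced recombination fractions.

Phenotype model: the phenotypic variance of each trait is normalized to 1;
each QTL's (additive, dominance) effect shape is rescaled so that its
expected variance share under 1:2:1 genotype frequencies equals its target
PVE, and the residual variance is 1 minus the summed PVEs. Residuals are
drawn jointly across traits with a configurable correlation matrix. Traits
are then shifted/scaled to colorimeter-like units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import A, B, H, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QTLSpec:
    """One simulated QTL: location, effect shape and target variance share.

    ``additive``/``dominance`` fix only the shape of the effect; the
    absolute scale is solved from ``pve`` (see module docstring).
    """

    chromosome: int  # 1-based index
    position_cM: float
    additive: float = 1.0
    dominance: float = 0.0
    pve: float = 0.2


def _default_qtl_spec() -> dict[str, list[QTLSpec]]:
    # Mirrors the study's architecture: a strong hotspot on one chromosome
    # shared across traits, 1-4 QTLs per trait, PVE up to ~0.40.
    return {
        "L": [QTLSpec(3, 45.0, 1.0, 0.0, 0.20),
              QTLSpec(9, 21.0, 1.0, 0.5, 0.40)],
        "a": [QTLSpec(5, 21.0, 1.0, 0.0, 0.12),
              QTLSpec(6, 80.0, 1.0, 0.0, 0.08),
              QTLSpec(9, 25.0, 1.0, 0.5, 0.25)],
        "b": [QTLSpec(3, 44.0, 1.0, 0.0, 0.10),
              QTLSpec(5, 21.0, 1.0, 0.0, 0.08),
              QTLSpec(9, 21.0, 1.0, 0.5, 0.30),
              QTLSpec(9, 29.0, 1.0, 0.0, 0.05)],
    }


def _default_trait_corr() -> np.ndarray:
    return np.array([[1.0, 0.5, 0.6],
                     [0.5, 1.0, 0.5],
                     [0.6, 0.5, 1.0]])


@dataclass
class SimConfig:
    """Parameters of the synthetic cross.

    Defaults emulate the study population: 13 chromosomes, 120 F2
    individuals, dense markers, correlated L/a/b phenotypes. The true
    miscall and missingness rates of low-coverage data are not published
    for this population; the defaults below are plausible values for
    ~1x coverage and are deliberately config-exposed, not asserted facts.
    """

    n_chromosomes: int = 13
    chrom_length_cM: float = 120.0
    n_individuals: int = 120
    marker_density: float = 2.0        # markers per cM
    miscall_run_rate: float = 0.10     # P(a true-H run acquires a miscall run)
    miscall_run_length: float = 3.0    # mean markers per miscall run
    missing_rate: float = 0.05
    qtl_spec: dict[str, list[QTLSpec]] = field(default_factory=_default_qtl_spec)
    trait_corr: np.ndarray = field(default_factory=_default_trait_corr)
    trait_means: dict[str, float] = field(
        default_factory=lambda: {"L": 40.0, "a": 5.0, "b": 10.0})
    trait_sds: dict[str, float] = field(
        default_factory=lambda: {"L": 8.40, "a": 2.67, "b": 4.27})
    bp_per_cM: float = 200_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miscall_run_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        tc = np.asarray(self.trait_corr, dtype=float)
        if tc.shape != (len(self.traits()), len(self.traits())):
            raise ValueError("trait_corr must be square, one row per trait")
        if not np.allclose(tc, tc.T):
            raise ValueError("trait_corr must be symmetric")
        try:
            np.linalg.cholesky(tc)
        except np.linalg.LinAlgError:
            raise ValueError("trait_corr must be positive definite") from None
        self.trait_corr = tc
        for trait, qtls in self.qtl_spec.items():
            total = sum(q.pve for q in qtls)
            if total >= 1.0:
                raise ValueError(f"summed PVE for {trait} must be < 1")
            for q in qtls:
                if not 0 <= q.position_cM <= self.chrom_length_cM:
                    raise ValueError(
                        f"QTL at {q.position_cM} cM beyond chromosome end")
                if not 1 <= q.chromosome <= self.n_chromosomes:
                    raise ValueError(f"QTL chromosome {q.chromosome} out of range")

    def traits(self) -> list[str]:
        return list(self.qtl_spec.keys()) if self.qtl_spec else ["L", "a", "b"]

    def contig_name(self, chromosome: int) -> str:
        return f"C{chromosome}"


@dataclass
class F2Truth:
    """Error-free ground truth of one simulated population."""

    true_matrix: GenotypeMatrix
    crossover_points: list[list[list[float]]]  # [individual][chromosome] -> cM
    qtl_genotypes: dict[str, np.ndarray]       # trait -> (n_qtl, n_individuals)
    marker_chromosome: np.ndarray              # 1-based, per marker
    marker_cM: np.ndarray

    def to_json(self, path) -> None:
        obj = {
            "crossover_points": self.crossover_points,
            "qtl_genotypes": {t: g.tolist() for t, g in self.qtl_genotypes.items()},
            "marker_chromosome": self.marker_chromosome.tolist(),
            "marker_cM": self.marker_cM.tolist(),
            "true_codes": self.true_matrix.codes.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def _gamete_alleles(positions: np.ndarray, length: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, list[float]]:
    """Allele (0/1 = parental origin) carried by one gamete at each position."""
    n_xo = rng.poisson(length / 100.0)
    xo = np.sort(rng.uniform(0.0, length, size=n_xo))
    start = rng.integers(0, 2)
    crossings = np.searchsorted(xo, positions, side="right")
    return (start + crossings) % 2, xo.tolist()


def simulate_f2(config: SimConfig
                ) -> tuple[F2Truth, GenotypeMatrix, pd.DataFrame]:
    """Simulate one F2 population.

    Returns the error-free truth, the noisy observed genotype matrix
    (miscall runs applied to true-H stretches, then uniform missingness),
    and the phenotype table (one row per individual, columns = traits).
    All outputs are a deterministic function of ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_individuals
    length = config.chrom_length_cM

    # Marker placement, shared across individuals.
    chrom_pos: list[np.ndarray] = []
    marker_rows = []
    for c in range(1, config.n_chromosomes + 1):
        n_mark = max(2, int(round(config.marker_density * length)))
        pos_cM = np.sort(rng.uniform(0.0, length, size=n_mark))
        chrom_pos.append(pos_cM)
        bp = np.round(pos_cM * config.bp_per_cM).astype(np.int64) + 1
        bp = np.maximum.accumulate(bp + np.arange(n_mark))  # strictly increasing
        for p_cM, p_bp in zip(pos_cM, bp):
            marker_rows.append((config.contig_name(c), int(p_bp), c, p_cM))

    markers = pd.DataFrame(marker_rows,
                           columns=["contig", "position", "chromosome", "cM"])
    n_markers = len(markers)

    true_codes = np.empty((n_markers, n_ind), dtype=np.int8)
    crossover_points: list[list[list[float]]] = []
    qtl_positions = {t: [(q.chromosome, q.position_cM) for q in qtls]
                     for t, qtls in config.qtl_spec.items()}
    qtl_geno = {t: np.empty((len(p), n_ind), dtype=np.int8)
                for t, p in qtl_positions.items()}

    offset = 0
    chrom_offsets = []
    for c in range(config.n_chromosomes):
        chrom_offsets.append(offset)
        offset += len(chrom_pos[c])

    for j in range(n_ind):
        per_chrom_xo: list[list[float]] = []
        for c in range(config.n_chromosomes):
            pos = chrom_pos[c]
            eval_pos = pos
            # Tack QTL positions onto the evaluation grid for this chromosome.
            extra = [(t, k, p) for t, plist in qtl_positions.items()
                     for k, (qc, p) in enumerate(plist) if qc == c + 1]
            if extra:
                eval_pos = np.concatenate([pos, [e[2] for e in extra]])
            g1, xo1 = _gamete_alleles(eval_pos, length, rng)
            g2, xo2 = _gamete_alleles(eval_pos, length, rng)
            geno = (g1 + g2).astype(np.int8)  # 0=A, 1=H, 2=B
            o = chrom_offsets[c]
            true_codes[o:o + len(pos), j] = geno[:len(pos)]
            for idx, (t, k, _p) in enumerate(extra):
                qtl_geno[t][k, j] = geno[len(pos) + idx]
            per_chrom_xo.append(sorted(xo1 + xo2))
        crossover_points.append(per_chrom_xo)

    individuals = [f"F2_{j + 1:03d}" for j in range(n_ind)]
    true_matrix = GenotypeMatrix(markers[["contig", "position"]].copy(),
                                 true_codes, individuals)
    truth = F2Truth(true_matrix, crossover_points, qtl_geno,
                    markers["chromosome"].to_numpy(),
                    markers["cM"].to_numpy())

    observed = _apply_noise(true_codes, markers["chromosome"].to_numpy(),
                            config, rng)
    obs_matrix = GenotypeMatrix(markers[["contig", "position"]].copy(),
                                observed, individuals)
    pheno = _simulate_phenotypes(config, qtl_geno, individuals, rng)
    return truth, obs_matrix, pheno


def _apply_noise(true_codes: np.ndarray, marker_chrom: np.ndarray,
                 config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Miscall runs on true-H stretches, then uniform missingness."""
    codes = true_codes.copy()
    n_markers, n_ind = codes.shape
    if config.miscall_run_rate > 0:
        p_geom = min(1.0, 1.0 / max(config.miscall_run_length, 1.0))
        for c in np.unique(marker_chrom):
            idx = np.flatnonzero(marker_chrom == c)
            for j in range(n_ind):
                col = codes[idx, j]
                is_h = col == H
                # Maximal runs of true heterozygotes.
                bounds = np.flatnonzero(np.diff(np.r_[0, is_h.view(np.int8), 0]))
                for s, e in zip(bounds[::2], bounds[1::2]):
                    if rng.random() >= config.miscall_run_rate:
                        continue
                    run_len = int(rng.geometric(p_geom))
                    start = int(rng.integers(s, e))
                    hom = A if rng.random() < 0.5 else B
                    col[start:min(start + run_len, e)] = hom
                codes[idx, j] = col
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = MISSING
    return codes


def _simulate_phenotypes(config: SimConfig, qtl_geno: dict[str, np.ndarray],
                         individuals: Sequence[str],
                         rng: np.random.Generator) -> pd.DataFrame:
    traits = config.traits()
    n_ind = len(individuals)
    resid_sd = np.array(
        [np.sqrt(1.0 - sum(q.pve for q in config.qtl_spec.get(t, [])))
         for t in traits])
    cov = np.outer(resid_sd, resid_sd) * config.trait_corr
    resid = rng.multivariate_normal(np.zeros(len(traits)), cov, size=n_ind,
                                    method="cholesky")
    values = {}
    for ti, t in enumerate(traits):
        y = resid[:, ti].copy()
        for k, q in enumerate(config.qtl_spec.get(t, [])):
            g = qtl_geno[t][k]
            x = g.astype(float) - 1.0          # additive: -1, 0, +1
            z = (g == H).astype(float)          # dominance indicator
            shape_var = q.additive ** 2 / 2.0 + q.dominance ** 2 / 4.0
            scale = np.sqrt(q.pve / shape_var) if shape_var > 0 else 0.0
            y += scale * (q.additive * x + q.dominance * (z - 0.5))
        values[t] = config.trait_means.get(t, 0.0) \
            + config.trait_sds.get(t, 1.0) * y
    df = pd.DataFrame(values, index=list(individuals))
    df.index.name = "individual"
    return df


def inject_isolated_errors(matrix: GenotypeMatrix, rate: float,
                           seed: int = 0) -> tuple[GenotypeMatrix, np.ndarray]:
    """Flip a random fraction of non-missing calls to a different code.

    Used to benchmark the sliding-window correction against a known error
    mask. Returns the corrupted matrix and the boolean mask of flips.
    """
    rng = np.random.default_rng(seed)
    codes = matrix.codes.copy()
    eligible = codes != MISSING
    mask = eligible & (rng.random(codes.shape) < rate)
    shift = rng.integers(1, 3, size=codes.shape)
    codes[mask] = (codes[mask] + shift[mask]) % 3
    out = GenotypeMatrix(matrix.markers.copy(), codes, matrix.individuals)
    return out, mask


# --------------------------------------------------------------------------
# Annotation fixtures: gene models, parent-line variants, DEG tables
# --------------------------------------------------------------------------

LATE_STAGES = (10, 15, 20, 25)
CONTROL_STAGE = 5
ALL_STAGES = (CONTROL_STAGE,) + LATE_STAGES


@dataclass
class SimGene:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    role: str  # "candidate", "decoy_<condition>", "background"


def simulate_annotation(config: SimConfig, n_genes: int,
                        n_planted_candidates: int, n_decoys: int = 0,
                        ) -> tuple[list[SimGene], pd.DataFrame, pd.DataFrame]:
    """Gene models, a parent-genotyped variant table, and DEG tables.

    Planted candidate genes carry one high-impact variant homozygous-alternate
    in the black parent and homozygous-reference in both white lines, are
    differentially expressed at at least one late stage (10/15/20/25 DAF)
    and not at the 5 DAF control. Decoy genes each violate exactly one of
    those three conditions (cycling through the violations); background
    genes carry no qualifying signal at all.

    Returns (genes, variant table, long-format DEG table).
    """
    if n_planted_candidates + n_decoys > n_genes:
        raise ValueError("planted + decoy genes exceed n_genes")
    rng = np.random.default_rng(config.seed + 7)
    genes: list[SimGene] = []
    gene_len = 3000
    spacing = 8000
    max_bp = int(config.chrom_length_cM * config.bp_per_cM)
    # Planted/decoy genes sit at the simulated QTL positions so that the
    # physical QTL segments recovered downstream actually contain them;
    # background genes fill a regular grid elsewhere.
    qtl_loci = sorted({(q.chromosome, q.position_cM)
                       for qtls in config.qtl_spec.values() for q in qtls})
    if not qtl_loci:
        qtl_loci = [(1, config.chrom_length_cM / 2.0)]
    used: dict[int, set[int]] = {}

    def place(chrom: int, slot: int) -> tuple[int, int, int]:
        slots = used.setdefault(chrom, set())
        while slot in slots or slot < 0 or (slot + 1) * spacing > max_bp:
            slot = slot + 1 if slot >= 0 else 0
        slots.add(slot)
        start = slot * spacing + 1000
        return chrom, start, start + gene_len - 1

    decoy_kinds = ["low_impact", "not_coseg", "deg_at_control", "no_late_deg"]
    n_special = n_planted_candidates + n_decoys
    k = 0
    for i in range(n_genes):
        if i < n_special:
            qc, qpos = qtl_loci[i % len(qtl_loci)]
            base_slot = int(qpos * config.bp_per_cM) // spacing
            chrom, start, end = place(qc, base_slot + i // len(qtl_loci))
            if i < n_planted_candidates:
                role = "candidate"
            else:
                role = f"decoy_{decoy_kinds[k % len(decoy_kinds)]}"
                k += 1
        else:
            chrom = (i - n_special) % config.n_chromosomes + 1
            chrom, start, end = place(chrom,
                                      (i - n_special) // config.n_chromosomes)
            role = "background"
        mid = start + gene_len // 2
        exons = [(start, mid - 200), (mid + 200, end)]
        genes.append(SimGene(f"G{i + 1:04d}", config.contig_name(chrom),
                             start, end, "+" if i % 2 == 0 else "-",
                             exons, role))

    variant_rows = []
    deg_rows = []
    for g in genes:
        pos = g.exons[0][0] + 10
        coseg = ("1/1", "0/0", "0/0")  # black, white, reference line
        role = g.role
        if role == "candidate":
            variant_rows.append((g.contig, pos, "C", "T", g.gene_id,
                                 "stop_gained", "high", *coseg))
        elif role == "decoy_low_impact":
            variant_rows.append((g.contig, pos, "C", "T", g.gene_id,
                                 "missense_variant", "moderate", *coseg))
        elif role == "decoy_not_coseg":
            variant_rows.append((g.contig, pos, "C", "T", g.gene_id,
                                 "stop_gained", "high", "1/1", "1/1", "0/0"))
        elif role in ("decoy_deg_at_control", "decoy_no_late_deg"):
            variant_rows.append((g.contig, pos, "C", "T", g.gene_id,
                                 "stop_gained", "high", *coseg))

        deg_late = role in ("candidate", "decoy_low_impact", "decoy_not_coseg",
                            "decoy_deg_at_control")
        deg_control = role == "decoy_deg_at_control"
        late_hits = set(rng.choice(LATE_STAGES,
                                   size=int(rng.integers(1, 4)),
                                   replace=False)) if deg_late else set()
        for stage in ALL_STAGES:
            is_deg = (stage == CONTROL_STAGE and deg_control) or \
                     (stage in late_hits)
            if is_deg:
                lfc = float(rng.uniform(1.5, 4.0)) * (1 if rng.random() < 0.5 else -1)
                padj = float(rng.uniform(1e-6, 0.01))
            else:
                lfc = float(rng.normal(0.0, 0.3))
                padj = float(rng.uniform(0.2, 1.0))
            deg_rows.append((g.gene_id, stage, lfc, padj))

    variants = pd.DataFrame(variant_rows, columns=[
        "contig", "position", "ref", "alt", "gene_id", "effect", "impact",
        "black", "white", "reference"])
    deg = pd.DataFrame(deg_rows, columns=["gene_id", "stage", "log2fc", "padj"])
    return genes, variants, deg


# --------------------------------------------------------------------------
# Plain-text writers (VCF / TSV / GFF3); coordinates 1-based inclusive
# --------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path, parent1: str = "P1_white",
              parent2: str = "P2_black") -> None:
    """Minimal GT-only biallelic VCF: parent 1 homozygous reference,
    parent 2 homozygous alternate at every marker."""
    gt_map = {A: "0/0", H: "0/1", B: "1/1", MISSING: "./."}
    contigs = matrix.markers["contig"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT", parent1, parent2] + matrix.individuals
        fh.write("\t".join(cols) + "\n")
        for i in range(matrix.n_markers):
            contig = matrix.markers["contig"].iat[i]
            pos = matrix.markers["position"].iat[i]
            gts = [gt_map[int(c)] for c in matrix.codes[i]]
            row = [contig, str(pos), f"{contig}-{pos}", "A", "G", ".", "PASS",
                   ".", "GT", "0/0", "1/1"] + gts
            fh.write("\t".join(row) + "\n")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t")


def write_gff3(genes: Sequence[SimGene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write("\t".join([g.contig, "sim", "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            mrna = f"{g.gene_id}.t1"
            fh.write("\t".join([g.contig, "sim", "mRNA", str(g.start),
                                str(g.end), ".", g.strand, ".",
                                f"ID={mrna};Parent={g.gene_id}"]) + "\n")
            for n, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([g.contig, "sim", "exon", str(s), str(e),
                                    ".", g.strand, ".",
                                    f"ID={mrna}.exon{n};Parent={mrna}"]) + "\n")
                fh.write("\t".join([g.contig, "sim", "CDS", str(s), str(e),
                                    ".", g.strand, "0",
                                    f"ID={mrna}.cds{n};Parent={mrna}"]) + "\n")


def write_deg_tables(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", index=False)


def write_variant_table(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)
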