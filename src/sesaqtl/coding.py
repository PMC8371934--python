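"""Genotype coding for an F2 intercross.

Joint-called biallelic variants for the two inbred parents and their F2
progeny are converted into the classic A/B/H coded marker matrix: ``A`` for
the first parent's homozygote, ``B`` for the second parent's, ``H`` for the
heterozygote. Only sites where both parents are homozygous for opposite
alleles are informative in an F2 and survive the selection step; everything
else about a progeny call that cannot be phased (missing, third allele)
degrades to missing rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Integer codes used throughout the package.
A, H, B, MISSING = 0, 1, 2, -1

CODE_TO_SYMBOL = {A: "A", H: "H", B: "B", MISSING: "-"}
SYMBOL_TO_CODE = {v: k for k, v in CODE_TO_SYMBOL.items()}


@dataclass
class VariantSite:
    """One biallelic site with parental and progeny diploid calls.

    Genotypes are allele-index pairs such as ``(0, 0)``, ``(0, 1)``;
    ``None`` (or a pair containing ``-1``) means missing.
    """

    contig: str
    position: int  # 1-based bp
    ref: str
    alt: str
    parent1_gt: tuple[int, int] | None
    parent2_gt: tuple[int, int] | None
    progeny_gts: list[tuple[int, int] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


class GenotypeMatrix:
    """Coded A/B/H marker matrix, markers x individuals.

    Parameters
    ----------
    markers : DataFrame with columns ``contig`` and ``position`` (1-based bp),
        sorted by (contig, position) within each contig block.
    codes : int8 array of shape (n_markers, n_individuals) with values in
        {0 (A), 1 (H), 2 (B), -1 (missing)}.
    individuals : sample names, one per column.
    """

    def __init__(self, markers: pd.DataFrame, codes: np.ndarray,
                 individuals: Sequence[str]):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or len(markers) != codes.shape[0]:
            raise ValueError("codes must be (n_markers, n_individuals)")
        if codes.shape[1] != len(individuals):
            raise ValueError("one column per individual required")
        for block in markers.groupby("contig", sort=False):
            if not block[1]["position"].is_monotonic_increasing:
                raise ValueError("markers must be sorted by position within contig")
        self.markers = markers.reset_index(drop=True)
        self.codes = codes
        self.individuals = list(individuals)

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]

    def marker_ids(self) -> list[str]:
        return [f"{c}-{p}" for c, p in
                zip(self.markers["contig"], self.markers["position"])]

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        """Write the matrix in the dialect consumed by the binning stage:
        rows = markers (``contig:pos`` ID), columns = individuals, symbols
        A/B/H/-."""
        sym = np.empty(self.codes.shape, dtype=object)
        for code, s in CODE_TO_SYMBOL.items():
            sym[self.codes == code] = s
        df = pd.DataFrame(sym, columns=self.individuals)
        df.insert(0, "marker", self.marker_ids())
        df.insert(1, "contig", self.markers["contig"].values)
        df.insert(2, "position", self.markers["position"].values)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        individuals = [c for c in df.columns
                       if c not in ("marker", "contig", "position")]
        sym = df[individuals].to_numpy(dtype=object)
        codes = np.full(sym.shape, MISSING, dtype=np.int8)
        for s, code in SYMBOL_TO_CODE.items():
            codes[sym == s] = code
        markers = df[["contig", "position"]].copy()
        return cls(markers, codes, individuals)


def _is_hom(gt: tuple[int, int] | None) -> bool:
    return gt is not None and gt[0] == gt[1] and gt[0] >= 0


def _is_missing(gt: tuple[int, int] | None) -> bool:
    return gt is None or gt[0] < 0 or gt[1] < 0


def select_informative_sites(sites: Iterable[VariantSite]) -> list[VariantSite]:
    """Keep sites where both parents are non-missing homozygotes for
    different alleles — the only configuration an F2 cross can phase."""
    out = []
    prev_key = None
    for s in sites:
        key = (s.contig, s.position)
        if prev_key is not None and prev_key[0] == key[0] and key[1] < prev_key[1]:
            raise ValueError("input sites must be sorted by (contig, position)")
        prev_key = key
        if _is_hom(s.parent1_gt) and _is_hom(s.parent2_gt) \
                and s.parent1_gt[0] != s.parent2_gt[0]:
            out.append(s)
    return out


def code_genotypes(sites: Sequence[VariantSite],
                   individuals: Sequence[str] | None = None) -> GenotypeMatrix:
    """Code progeny calls at informative sites as A/H/B.

    Parent 1's homozygote codes ``A``, parent 2's ``B``, the heterozygote
    ``H``. Missing or inconsistent calls (an allele carried by neither
    parent's homozygote) code as missing; inconsistencies are tallied and
    logged, never raised — they are expected joint-calling noise that the
    downstream correction stage absorbs.
    """
    if not sites:
        raise ValueError("no informative sites to code")
    n_ind = len(sites[0].progeny_gts)
    if individuals is None:
        individuals = [f"F2_{i + 1:03d}" for i in range(n_ind)]
    codes = np.full((len(sites), n_ind), MISSING, dtype=np.int8)
    n_inconsistent = 0
    for i, s in enumerate(sites):
        a1 = s.parent1_gt[0]
        a2 = s.parent2_gt[0]
        for j, gt in enumerate(s.progeny_gts):
            if _is_missing(gt):
                continue
            alleles = frozenset(gt)
            if alleles == {a1}:
                codes[i, j] = A
            elif alleles == {a2}:
                codes[i, j] = B
            elif alleles == {a1, a2}:
                codes[i, j] = H
            else:
                n_inconsistent += 1
    if n_inconsistent:
        logger.info("code_genotypes: %d progeny calls inconsistent with "
                    "parental alleles, coded missing", n_inconsistent)
    markers = pd.DataFrame({
        "contig": [s.contig for s in sites],
        "position": [s.position for s in sites],
    })
    return GenotypeMatrix(markers, codes, individuals)


def read_vcf(path, parent1: str, parent2: str) -> list[VariantSite]:
    """Read biallelic sites from a VCF (GT field only).

    Multiallelic records are skipped with a warning; coding is defined only
    for biallelic sites.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        i1, i2 = samples.index(parent1), samples.index(parent2)
    except ValueError as e:
        raise ValueError(f"parent sample not found in VCF: {e}") from None
    progeny_idx = [i for i in range(len(samples)) if i not in (i1, i2)]
    sites: list[VariantSite] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = [tuple(g[:2]) for g in rec.genotypes]
        def clean(gt):
            return None if gt[0] < 0 or gt[1] < 0 else (int(gt[0]), int(gt[1]))
        sites.append(VariantSite(
            contig=rec.CHROM, position=rec.POS, ref=rec.REF, alt=rec.ALT[0],
            parent1_gt=clean(gts[i1]), parent2_gt=clean(gts[i2]),
            progeny_gts=[clean(gts[i]) for i in progeny_idx]))
    if n_multi:
        logger.warning("read_vcf: skipped %d multiallelic records", n_multi)
    return sites


def progeny_names_from_vcf(path, parent1: str, parent2: str) -> list[str]:
    from cyvcf2 import VCF
    samples = list(VCF(str(path)).samples)
    return [s for s in samples if s not in (parent1, parent2)]
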