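"""Linkage-map construction from bins of an F2 intercross.

The recombination fraction between two codominant markers is estimated by
maximum likelihood with an EM iteration over the phase-ambiguous
double-heterozygote class, the classic estimator for an F2 design: an
individual that is heterozygous at both loci may carry zero or two
recombinant gametes, and the E-step allocates it between those cases in
proportion to (1-r)^2 : r^2. The linkage LOD is the log10 likelihood ratio
of the fitted r against independence (r = 0.5); bins are clustered into
linkage groups by single linkage over pairs with LOD at or above a
threshold (default 12), groups below a minimum marker count are discarded,
and within-group order follows the physical order of the genome-anchored
bins. Adjacent-bin recombination fractions are converted to centimorgans
with the Kosambi mapping function and accumulated from zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .binning import Bin
from .coding import A, B, H

logger = logging.getLogger(__name__)

_EPS_R = 1e-9


@dataclass
class RecombEstimate:
    r: float
    lod: float
    n_informative: int


@dataclass
class LinkageGroup:
    id: int
    bins: list[Bin]
    cM_positions: list[float] = field(default_factory=list)

    @property
    def length_cM(self) -> float:
        return self.cM_positions[-1] if self.cM_positions else 0.0

    @property
    def n_markers(self) -> int:
        return sum(b.n_markers for b in self.bins)


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    mapping_function: str = "kosambi"

    def group_by_id(self, gid: int) -> LinkageGroup:
        for g in self.groups:
            if g.id == gid:
                return g
        raise KeyError(f"no linkage group {gid}")


# --------------------------------------------------------------- pairwise r

def _pair_counts(codesA: np.ndarray, codesB: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over individuals non-missing at both."""
    counts = np.zeros((3, 3), dtype=float)
    for ca in (A, H, B):
        for cb in (A, H, B):
            counts[ca, cb] = np.sum((codesA == ca) & (codesB == cb))
    return counts


def _cell_probs(r: np.ndarray) -> np.ndarray:
    """F2 two-locus genotype probabilities (3x3, indexed by A/H/B at each
    locus) under no interference; broadcastable over r."""
    r = np.asarray(r, dtype=float)
    p = 1.0 - r
    out = np.empty(r.shape + (3, 3), dtype=float)
    out[..., A, A] = out[..., B, B] = p * p / 4.0
    out[..., A, B] = out[..., B, A] = r * r / 4.0
    out[..., A, H] = out[..., H, A] = r * p / 2.0
    out[..., B, H] = out[..., H, B] = r * p / 2.0
    out[..., H, H] = (p * p + r * r) / 2.0
    return out


def _loglik(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    probs = np.clip(_cell_probs(r), 1e-300, None)
    return np.sum(counts * np.log(probs), axis=(-2, -1))


def _em_r(counts: np.ndarray, r0: float = 0.25, tol: float = 1e-8,
          max_iter: int = 500) -> np.ndarray:
    """Vectorized EM over stacked 3x3 count tables (shape (..., 3, 3))."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1))
    n_safe = np.where(n > 0, n, 1.0)
    one_rec = (counts[..., A, H] + counts[..., H, A]
               + counts[..., B, H] + counts[..., H, B])
    two_rec = counts[..., A, B] + counts[..., B, A]
    hh = counts[..., H, H]
    r = np.full(n.shape, r0, dtype=float)
    for _ in range(max_iter):
        p = 1.0 - r
        w = r * r / np.maximum(p * p + r * r, 1e-300)  # E[HH is double-recomb]
        r_new = (one_rec + 2.0 * two_rec + 2.0 * w * hh) / (2.0 * n_safe)
        r_new = np.clip(r_new, 0.0, 0.5)
        delta = np.max(np.abs(r_new - r))
        r = r_new
        if delta < tol:
            break
    return r


def estimate_rf_em(codesA: np.ndarray, codesB: np.ndarray) -> RecombEstimate:
    """Maximum-likelihood recombination fraction between two bins.

    Returns r-hat in [0, 0.5] and LOD = log10 L(r-hat) - log10 L(0.5),
    computed from individuals non-missing at both bins.
    """
    counts = _pair_counts(np.asarray(codesA), np.asarray(codesB))
    n = int(counts.sum())
    if n < 2:
        raise ValueError("need at least 2 jointly informative individuals")
    r = float(_em_r(counts))
    lod = float((_loglik(counts, np.array(r))
                 - _loglik(counts, np.array(0.5))) / np.log(10.0))
    return RecombEstimate(r=r, lod=max(lod, 0.0), n_informative=n)


def pairwise_rf(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs recombination fractions and linkage LODs.

    ``codes`` is (n_bins, n_individuals); returns (r, lod, n_informative)
    matrices of shape (n_bins, n_bins). Pairs with fewer than 2 jointly
    informative individuals get r = 0.5, lod = 0.
    """
    ind = {c: (codes == c).astype(np.float64) for c in (A, H, B)}
    nb = codes.shape[0]
    counts = np.empty((nb, nb, 3, 3), dtype=float)
    for ca in (A, H, B):
        for cb in (A, H, B):
            counts[:, :, ca, cb] = ind[ca] @ ind[cb].T
    n = counts.sum(axis=(-2, -1))
    r = _em_r(counts)
    lod = (_loglik(counts, r) - _loglik(counts, np.full_like(r, 0.5))) \
        / np.log(10.0)
    lod = np.maximum(lod, 0.0)
    bad = n < 2
    r[bad], lod[bad] = 0.5, 0.0
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    return r, lod, n.astype(int)


# ------------------------------------------------------------------ Kosambi

def kosambi_cM(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM.

    Values of r at or above 0.5 - 1e-6 are capped there with a warning;
    negative r raises.
    """
    scalar = np.isscalar(r)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be non-negative")
    cap = 0.5 - 1e-6
    if np.any(r >= cap):
        warnings.warn("recombination fraction at/above 0.5 capped for "
                      "Kosambi transform", stacklevel=2)
        r = np.minimum(r, cap)
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if scalar else d


def kosambi_inverse(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = tanh(d/50) / 2."""
    scalar = np.isscalar(d)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if scalar else r


# ----------------------------------------------------------------- grouping

def group_bins(bins: list[Bin], lod_threshold: float = 12.0,
               min_group_size: int = 100,
               contig_order: list[str] | None = None) -> GeneticMap:
    """Single-linkage clustering of bins into linkage groups.

    Pairs with linkage LOD >= ``lod_threshold`` are connected; groups whose
    summed underlying marker count is below ``min_group_size`` are
    discarded (logged). Within each group, bins are ordered physically:
    by contig (input order, or ``contig_order``) then start position.
    """
    if not bins:
        return GeneticMap([])
    codes = np.stack([b.codes for b in bins])
    _, lod, _ = pairwise_rf(codes)
    adj = csr_matrix(lod >= lod_threshold)
    n_comp, labels = connected_components(adj, directed=False)
    if contig_order is None:
        contig_order = list(dict.fromkeys(b.contig for b in bins))
    contig_rank = {c: i for i, c in enumerate(contig_order)}
    groups: list[LinkageGroup] = []
    gid = 0
    for comp in range(n_comp):
        members = [bins[i] for i in np.flatnonzero(labels == comp)]
        n_markers = sum(b.n_markers for b in members)
        if n_markers < min_group_size:
            logger.info("group_bins: discarding group with %d markers "
                        "(< %d)", n_markers, min_group_size)
            continue
        members.sort(key=lambda b: (contig_rank.get(b.contig, len(contig_rank)),
                                    b.start_bp))
        gid += 1
        groups.append(LinkageGroup(id=gid, bins=members))
    return GeneticMap(groups)


def space_group(group: LinkageGroup) -> LinkageGroup:
    """Assign cumulative Kosambi cM positions along a physically ordered
    group, starting at 0."""
    if not group.bins:
        group.cM_positions = []
        return group
    positions = [0.0]
    for left, right in zip(group.bins, group.bins[1:]):
        est = estimate_rf_em(left.codes, right.codes)
        positions.append(positions[-1] + kosambi_cM(est.r))
    group.cM_positions = positions
    return group


def space_map(gmap: GeneticMap) -> GeneticMap:
    for g in gmap.groups:
        space_group(g)
    return gmap


# -------------------------------------------------------------- statistics

@dataclass
class MapStats:
    """Per-group and total map characteristics.

    ``per_group`` columns: group, length_cM, n_bins, n_markers,
    mean_interval_cM (= length / (bins - 1)), n_gaps, largest_gap_cM.
    Density figures are ratios of the totals.
    """

    per_group: pd.DataFrame
    gap_threshold: float

    @property
    def total_length_cM(self) -> float:
        return float(self.per_group["length_cM"].sum())

    @property
    def total_bins(self) -> int:
        return int(self.per_group["n_bins"].sum())

    @property
    def total_markers(self) -> int:
        return int(self.per_group["n_markers"].sum())

    @property
    def bins_per_cM(self) -> float:
        return self.total_bins / self.total_length_cM

    @property
    def markers_per_cM(self) -> float:
        return self.total_markers / self.total_length_cM

    @property
    def markers_per_bin(self) -> float:
        return self.total_markers / self.total_bins

    @property
    def n_gaps(self) -> int:
        return int(self.per_group["n_gaps"].sum())

    @property
    def largest_gap_cM(self) -> float:
        return float(self.per_group["largest_gap_cM"].max())

    def summary_frame(self) -> pd.DataFrame:
        totals = pd.DataFrame([{
            "group": "Total", "length_cM": self.total_length_cM,
            "n_bins": self.total_bins, "n_markers": self.total_markers,
            "mean_interval_cM": self.total_length_cM
            / max(self.total_bins - len(self.per_group), 1),
            "n_gaps": self.n_gaps, "largest_gap_cM": self.largest_gap_cM}])
        return pd.concat([self.per_group, totals], ignore_index=True)


def map_stats(gmap: GeneticMap, gap_threshold: float = 5.0) -> MapStats:
    rows = []
    for g in gmap.groups:
        pos = np.asarray(g.cM_positions)
        gaps = np.diff(pos) if len(pos) > 1 else np.array([0.0])
        rows.append({
            "group": g.id,
            "length_cM": float(pos[-1]) if len(pos) else 0.0,
            "n_bins": len(g.bins),
            "n_markers": g.n_markers,
            "mean_interval_cM": (float(pos[-1]) / (len(g.bins) - 1)
                                 if len(g.bins) > 1 else 0.0),
            "n_gaps": int(np.sum(gaps >= gap_threshold)),
            "largest_gap_cM": float(gaps.max()) if len(gaps) else 0.0,
        })
    return MapStats(pd.DataFrame(rows), gap_threshold)


def marker_densities(total_length_cM: float, n_bins: int,
                     n_markers: int) -> dict[str, float]:
    """Bins/cM, markers/cM and markers/bin from map totals."""
    return {
        "bins_per_cM": n_bins / total_length_cM,
        "markers_per_cM": n_markers / total_length_cM,
        "markers_per_bin": n_markers / n_bins,
    }


# ------------------------------------------------------------------- I/O

def map_to_dataframe(gmap: GeneticMap) -> pd.DataFrame:
    rows = []
    for g in gmap.groups:
        for b, cm in zip(g.bins, g.cM_positions):
            rows.append({"bin_id": b.marker_id, "group": g.id,
                         "cM": round(cm, 2), "contig": b.contig,
                         "start_bp": b.start_bp, "end_bp": b.end_bp,
                         "n_markers": b.n_markers})
    return pd.DataFrame(rows)


def write_map_tsv(gmap: GeneticMap, path) -> None:
    map_to_dataframe(gmap).to_csv(path, sep="\t", index=False)
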