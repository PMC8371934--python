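"""Bin-map construction from a coded F2 genotype matrix.

Four steps, in order:

1. ``collapse_redundant`` — merge runs of consecutive markers that carry
   identical segregation information and sit within a minimum bp gap of each
   other into one representative marker;
2. ``window_correct`` — repair isolated genotyping errors by majority vote
   in a sliding window of (by default) 15 representative markers;
3. ``build_bins`` — merge adjacent representatives whose corrected vectors
   are compatible into bins, the mapping units of the linkage map;
4. ``filter_distorted`` — drop bins with distorted segregation (fewer than
   20 plants of either homozygote, or fewer than 40 heterozygous plants,
   out of 120).

Two genotype vectors are treated as redundant when they agree at every
individual where both are non-missing; requiring exact equality would let
low-coverage missingness shatter true bins. The window correction is a
single non-iterative pass computed entirely from the input state, and
overwrites a call only on a strict majority (> half the non-missing window
entries), which protects genuine crossover boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import A, B, H, MISSING, GenotypeMatrix, CODE_TO_SYMBOL, SYMBOL_TO_CODE

logger = logging.getLogger(__name__)


@dataclass
class RepresentativeMarker:
    contig: str
    position: int                 # bp of the run's first member
    member_positions: list[int]   # sorted bp of all merged markers
    codes: np.ndarray             # per-individual int8

    @property
    def n_markers(self) -> int:
        return len(self.member_positions)


@dataclass
class Bin:
    contig: str
    start_bp: int
    end_bp: int
    n_markers: int
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        c = self.codes
        return (int((c == A).sum()), int((c == H).sum()),
                int((c == B).sum()), int((c == MISSING).sum()))

    @property
    def marker_id(self) -> str:
        return f"{self.contig}-{self.start_bp}"


def _compatible(consensus: np.ndarray, codes: np.ndarray) -> bool:
    both = (consensus != MISSING) & (codes != MISSING)
    return bool(np.all(consensus[both] == codes[both]))


def _merge_into(consensus: np.ndarray, codes: np.ndarray) -> None:
    fill = (consensus == MISSING) & (codes != MISSING)
    consensus[fill] = codes[fill]


def collapse_redundant(matrix: GenotypeMatrix,
                       min_gap_bp: int = 100) -> list[RepresentativeMarker]:
    """Step 1: collapse runs of redundant markers closer than ``min_gap_bp``.

    A run extends while the next marker is < ``min_gap_bp`` downstream of the
    previous member and its vector is redundant with every member so far
    (equivalently, with the run's running consensus). The representative
    code per individual is the run consensus; missing entries are filled
    from the run's non-missing members.
    """
    reps: list[RepresentativeMarker] = []
    contigs = matrix.markers["contig"].to_numpy()
    positions = matrix.markers["position"].to_numpy()
    cur: RepresentativeMarker | None = None
    for i in range(matrix.n_markers):
        codes = matrix.codes[i]
        if (cur is not None and contigs[i] == cur.contig
                and positions[i] - cur.member_positions[-1] < min_gap_bp
                and _compatible(cur.codes, codes)):
            _merge_into(cur.codes, codes)
            cur.member_positions.append(int(positions[i]))
        else:
            cur = RepresentativeMarker(str(contigs[i]), int(positions[i]),
                                       [int(positions[i])], codes.copy())
            reps.append(cur)
    return reps


def window_correct(reps: list[RepresentativeMarker], window: int = 15,
                   return_audit: bool = False):
    """Step 2: single-pass sliding-window majority correction.

    For each representative and individual, the centered window of
    ``window`` markers (shrunk at contig edges, center included) votes over
    its non-missing entries. A non-missing center that disagrees with a
    strict-majority code is replaced; a missing center with a strict
    majority is imputed; ties leave the call unchanged. All decisions are
    computed from the input state, so the pass is order-independent.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    hw = window // 2
    out: list[RepresentativeMarker] = []
    audit_rows = []
    # Group contiguous blocks per contig, preserving order.
    blocks: list[list[int]] = []
    for i, r in enumerate(reps):
        if blocks and reps[blocks[-1][-1]].contig == r.contig:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    for block in blocks:
        codes = np.stack([reps[i].codes for i in block])  # (m, n_ind)
        m = codes.shape[0]
        # Windowed code counts via cumulative sums.
        cum = {c: np.cumsum(np.r_[np.zeros((1, codes.shape[1]), dtype=np.int32),
                                  (codes == c).astype(np.int32)], axis=0)
               for c in (A, H, B)}
        lo = np.maximum(np.arange(m) - hw, 0)
        hi = np.minimum(np.arange(m) + hw + 1, m)
        counts = np.stack([cum[c][hi] - cum[c][lo] for c in (A, H, B)])  # (3,m,n)
        nonmiss = counts.sum(axis=0)
        best = counts.max(axis=0)
        argbest = counts.argmax(axis=0)  # 0->A,1->H,2->B (code values coincide)
        strict = best * 2 > nonmiss
        new_codes = codes.copy()
        replace = strict & (codes != argbest)
        new_codes[replace] = argbest[replace]
        for i_local, i_global in enumerate(block):
            changed = np.flatnonzero(new_codes[i_local] != codes[i_local])
            for j in changed:
                audit_rows.append((reps[i_global].contig,
                                   reps[i_global].position,
                                   j,
                                   CODE_TO_SYMBOL[int(codes[i_local, j])],
                                   CODE_TO_SYMBOL[int(new_codes[i_local, j])]))
            out.append(RepresentativeMarker(
                reps[i_global].contig, reps[i_global].position,
                list(reps[i_global].member_positions),
                new_codes[i_local].astype(np.int8)))
    if return_audit:
        audit = pd.DataFrame(audit_rows, columns=[
            "contig", "position", "individual_index", "old", "new"])
        return out, audit
    return out


def build_bins(reps: list[RepresentativeMarker]) -> list[Bin]:
    """Step 3: merge adjacent representatives with compatible corrected
    vectors into bins; ``n_markers`` sums the underlying original markers."""
    bins: list[Bin] = []
    consensus: np.ndarray | None = None
    members: list[RepresentativeMarker] = []

    def flush():
        if members:
            bins.append(Bin(members[0].contig,
                            members[0].member_positions[0],
                            members[-1].member_positions[-1],
                            sum(r.n_markers for r in members),
                            consensus.astype(np.int8)))

    for r in reps:
        if members and r.contig == members[0].contig \
                and _compatible(consensus, r.codes):
            _merge_into(consensus, r.codes)
            members.append(r)
        else:
            flush()
            consensus = r.codes.copy()
            members = [r]
    flush()
    return bins


def filter_distorted(bins: list[Bin], min_hom: int = 20,
                     min_het: int = 40) -> list[Bin]:
    """Step 4: remove bins with distorted segregation.

    A bin is dropped iff nA < ``min_hom`` or nB < ``min_hom`` or
    nH < ``min_het`` (the disjunction reproduces the requirement of at
    least 20 + 40 + 20 = 80 informative plants under an ideal 1:2:1 ratio).
    """
    kept: list[Bin] = []
    n_dropped = 0
    for b in bins:
        nA, nH_, nB, _ = b.counts
        if nA < min_hom or nB < min_hom or nH_ < min_het:
            n_dropped += 1
            logger.debug("filter_distorted: dropping %s (A=%d H=%d B=%d)",
                         b.marker_id, nA, nH_, nB)
        else:
            kept.append(b)
    if n_dropped:
        logger.info("filter_distorted: removed %d of %d bins",
                    n_dropped, len(bins))
    return kept


def make_bin_map(matrix: GenotypeMatrix, min_gap_bp: int = 100,
                 window: int = 15, min_hom: int = 20,
                 min_het: int = 40) -> list[Bin]:
    """Run the full four-step pipeline on a coded matrix."""
    reps = collapse_redundant(matrix, min_gap_bp=min_gap_bp)
    reps = window_correct(reps, window=window)
    bins = build_bins(reps)
    return filter_distorted(bins, min_hom=min_hom, min_het=min_het)


# ------------------------------------------------------------------- I/O

def bins_to_dataframe(bins: list[Bin], individuals=None) -> pd.DataFrame:
    rows = []
    for k, b in enumerate(bins):
        nA, nH_, nB, nMiss = b.counts
        rows.append({
            "bin_id": f"bin{k + 1:05d}", "contig": b.contig,
            "start_bp": b.start_bp, "end_bp": b.end_bp,
            "n_markers": b.n_markers, "nA": nA, "nH": nH_, "nB": nB,
            "nMissing": nMiss,
            "codes": "".join(CODE_TO_SYMBOL[int(c)] for c in b.codes)})
    return pd.DataFrame(rows)


def write_bins_tsv(bins: list[Bin], path) -> None:
    bins_to_dataframe(bins).to_csv(path, sep="\t", index=False)


def read_bins_tsv(path) -> list[Bin]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    out = []
    for _, row in df.iterrows():
        codes = np.array([SYMBOL_TO_CODE[s] for s in row["codes"]],
                         dtype=np.int8)
        out.append(Bin(row["contig"], int(row["start_bp"]), int(row["end_bp"]),
                       int(row["n_markers"]), codes))
    return out
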