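"""Consolidation of per-trait QTL calls into non-overlapping intervals and
clustered hotspot ("qSC") intervals, and projection to physical segments.

Overlap is tested on half-open [start, end) ranges: endpoint-touching
intervals stay distinct (which is what keeps a hotspot's internal
boundaries visible), while genuinely overlapping or nested intervals merge
to their union. Zero-length calls — single-marker QTLs whose left and
right boundary coincide — have an empty half-open range; they are absorbed
into any consolidated interval whose closed extent contains the point and
otherwise stand alone. cM values are carried at 2-decimal precision as
integers of hundredths, so interval arithmetic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genmap import GeneticMap
from .qtlscan import QTLCall


def _to_hund(x: float) -> int:
    return int(round(float(x) * 100.0))


@dataclass
class GeneticInterval:
    group: int
    start_cM: float
    end_cM: float
    qtls: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if _to_hund(self.start_cM) > _to_hund(self.end_cM):
            raise ValueError("interval start > end")

    @property
    def _key(self) -> tuple[int, int, int]:
        return (self.group, _to_hund(self.start_cM), _to_hund(self.end_cM))


@dataclass
class PhysicalSegment:
    contig: str
    start_bp: int
    end_bp: int
    source: GeneticInterval | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start > end")

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _normalize_calls(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    rows = []
    for c in calls:
        if isinstance(c, QTLCall):
            rows.append({"trait": c.trait, "group": c.group, "qtl": c.name,
                         "left_cM": c.left_cM, "right_cM": c.right_cM})
        else:  # (trait, group, name, left, right) tuples
            rows.append({"trait": c[0], "group": c[1], "qtl": c[2],
                         "left_cM": c[3], "right_cM": c[4]})
    return pd.DataFrame(rows)


def merge_overlapping(calls) -> list[GeneticInterval]:
    """Collapse per-trait QTL boundary intervals into disjoint intervals.

    Accepts QTLCall objects, (trait, group, name, left_cM, right_cM)
    tuples, or an equivalent DataFrame. Identical intervals are
    deduplicated; half-open-overlapping intervals merge to their union;
    zero-length calls are attached to the consolidated interval containing
    them. Output is sorted and pairwise disjoint, each interval annotated
    with all supporting QTLs and traits.
    """
    df = _normalize_calls(calls)
    out: list[GeneticInterval] = []
    for gid, sub in df.groupby("group", sort=True):
        items = []
        for _, row in sub.iterrows():
            s, e = _to_hund(row["left_cM"]), _to_hund(row["right_cM"])
            if s > e:
                raise ValueError(
                    f"QTL {row['qtl']}: left boundary beyond right")
            items.append((s, e, str(row["qtl"]), str(row["trait"])))
        proper = sorted([it for it in items if it[0] < it[1]])
        points = [it for it in items if it[0] == it[1]]
        merged: list[list] = []
        for s, e, q, t in proper:
            if merged and s < merged[-1][1]:  # half-open overlap
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2].append(q)
                merged[-1][3].append(t)
            else:
                merged.append([s, e, [q], [t]])
        for s, e, q, t in points:
            host = next((m for m in merged if m[0] <= s <= m[1]), None)
            if host is not None:
                host[2].append(q)
                host[3].append(t)
            else:
                merged.append([s, e, [q], [t]])
        merged.sort()
        for s, e, qs, ts in merged:
            out.append(GeneticInterval(int(gid), s / 100.0, e / 100.0,
                                       qs, sorted(set(ts))))
    return out


def cluster_adjacent(intervals: Sequence[GeneticInterval],
                     max_gap: float = 2.0) -> list[GeneticInterval]:
    """Merge chains of disjoint intervals separated by <= ``max_gap`` cM
    into one spanning interval per chain (the hotspot/"qSC" consolidation).
    With ``max_gap = 0`` only endpoint-touching intervals merge."""
    gap_h = _to_hund(max_gap)
    by_group: dict[int, list[GeneticInterval]] = {}
    for iv in intervals:
        by_group.setdefault(iv.group, []).append(iv)
    out: list[GeneticInterval] = []
    for gid in sorted(by_group):
        ivs = sorted(by_group[gid], key=lambda v: v._key)
        cur: list | None = None
        for iv in ivs:
            s, e = _to_hund(iv.start_cM), _to_hund(iv.end_cM)
            if cur is not None and s - cur[1] <= gap_h:
                cur[1] = max(cur[1], e)
                cur[2].extend(iv.qtls)
                cur[3].extend(iv.traits)
            else:
                if cur is not None:
                    out.append(GeneticInterval(gid, cur[0] / 100.0,
                                               cur[1] / 100.0, cur[2],
                                               sorted(set(cur[3]))))
                cur = [s, e, list(iv.qtls), list(iv.traits)]
        if cur is not None:
            out.append(GeneticInterval(gid, cur[0] / 100.0, cur[1] / 100.0,
                                       cur[2], sorted(set(cur[3]))))
    return out


def parse_marker_id(marker_id: str) -> tuple[str, int]:
    """Recover (contig, bp) from a ``<contig>-<bp>`` marker name (the
    contig itself may contain hyphens/underscores; the final field is bp)."""
    contig, bp = marker_id.rsplit("-", 1)
    return contig, int(bp)


def to_physical(interval: GeneticInterval,
                gmap: GeneticMap) -> list[PhysicalSegment]:
    """Project a genetic interval to the bp ranges spanned by its bins,
    one segment per contig (closed-endpoint inclusion of boundary bins)."""
    grp = gmap.group_by_id(interval.group)
    s, e = _to_hund(interval.start_cM), _to_hund(interval.end_cM)
    segs: list[PhysicalSegment] = []
    cur_contig = None
    cur_lo = cur_hi = 0
    found = False
    for b, cm in zip(grp.bins, grp.cM_positions):
        if not (s <= _to_hund(cm) <= e):
            continue
        found = True
        if b.contig == cur_contig:
            cur_lo = min(cur_lo, b.start_bp)
            cur_hi = max(cur_hi, b.end_bp)
        else:
            if cur_contig is not None:
                segs.append(PhysicalSegment(cur_contig, cur_lo, cur_hi,
                                            interval))
            cur_contig, cur_lo, cur_hi = b.contig, b.start_bp, b.end_bp
    if cur_contig is not None:
        segs.append(PhysicalSegment(cur_contig, cur_lo, cur_hi, interval))
    if not found:
        raise ValueError(
            f"interval {interval.start_cM}-{interval.end_cM} cM on group "
            f"{interval.group} contains no bins")
    return segs


# ------------------------------------------------------------------- I/O

def intervals_to_dataframe(intervals: Sequence[GeneticInterval]
                           ) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": iv.group, "start_cM": round(iv.start_cM, 2),
        "end_cM": round(iv.end_cM, 2), "qtls": ",".join(iv.qtls),
        "traits": ",".join(iv.traits)} for iv in intervals])


def write_intervals_tsv(intervals: Sequence[GeneticInterval], path) -> None:
    intervals_to_dataframe(intervals).to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: Sequence[PhysicalSegment], path) -> None:
    """BED (0-based half-open) of physical segments."""
    with open(path, "w") as fh:
        for seg in segments:
            name = "."
            if seg.source is not None:
                name = (f"LG{seg.source.group}:{seg.source.start_cM:.2f}-"
                        f"{seg.source.end_cM:.2f}cM")
            fh.write(f"{seg.contig}\t{seg.start_bp - 1}\t{seg.end_bp}"
                     f"\t{name}\n")
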