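"""Bundled summary tables of the sesame seed-coat-color F2 study
population.

Two small reference tables ship with the package: the per-linkage-group
characteristics of the 22,375-bin superdense map (length, bin and marker
counts, gap statistics) and the reported boundaries of the 17 seed-coat
color QTLs (L/a/b colorimeter indices) on linkage groups 3, 5, 6 and 9.
They serve as worked-example inputs for the interval-consolidation and
map-statistics operations; the underlying population-scale sequencing data
are not distributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Marker/bin counts of the previous-generation sesame map that the
#: superdense map superseded, used to express the density improvement.
PREVIOUS_MAP_BINS = 3_041
PREVIOUS_MAP_MARKERS = 30_193


def _read(name: str) -> pd.DataFrame:
    with resources.files("sesaqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_map_stats() -> pd.DataFrame:
    """Per-linkage-group map characteristics (13 rows): length_cM, n_bins,
    n_markers, avg_interval_cM, n_gaps, largest_gap_cM."""
    return _read("sesame_f2_map_stats.tsv")


def load_qtl_table() -> pd.DataFrame:
    """The 17 reported seed-coat-color QTLs with flanking-marker names and
    cM boundaries (columns trait, group, qtl, left_marker, left_cM,
    right_marker, right_cM, ...)."""
    return _read("sesame_f2_qtls.tsv")
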