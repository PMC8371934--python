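"""Bin-map construction: redundant-marker collapsing, sliding-window
correction, bin grouping and the segregation-distortion filter."""

import numpy as np
import pandas as pd
import pytest

from conftest import single_trait_config
from sesaqtl.binning import (Bin, build_bins, collapse_redundant,
                             filter_distorted, window_correct)
from sesaqtl.coding import A, B, H, MISSING, GenotypeMatrix
from sesaqtl.simdata import inject_isolated_errors, simulate_f2


def matrix_from(codes, positions, contig="C1"):
    codes = np.asarray(codes, dtype=np.int8)
    markers = pd.DataFrame({"contig": [contig] * len(positions),
                            "position": positions})
    inds = [f"i{k}" for k in range(codes.shape[1])]
    return GenotypeMatrix(markers, codes, inds)


# ----------------------------------------------------------- collapsing

def test_identical_markers_within_gap_collapse():
    m = matrix_from([[A, H, B], [A, H, B]], [100, 150])
    assert len(collapse_redundant(m, min_gap_bp=100)) == 1


def test_identical_markers_beyond_gap_stay_separate():
    m = matrix_from([[A, H, B], [A, H, B]], [100, 250])
    assert len(collapse_redundant(m, min_gap_bp=100)) == 2


def test_consensus_fills_missing_from_run():
    m = matrix_from([[A, H, B], [A, MISSING, B], [A, H, B]],
                    [100, 150, 200])
    reps = collapse_redundant(m)
    assert len(reps) == 1
    assert list(reps[0].codes) == [A, H, B]
    assert reps[0].n_markers == 3


def test_conflicting_marker_breaks_run():
    m = matrix_from([[A, H, B], [A, H, A]], [100, 150])
    assert len(collapse_redundant(m)) == 2


def test_collapse_matches_brute_force_runs():
    """Greedy consensus collapsing equals a brute-force enumeration of
    maximal pairwise-compatible runs on random noisy vectors."""
    rng = np.random.default_rng(0)
    n_ind, n_mark = 8, 40
    base = rng.integers(0, 3, size=(1, n_ind))
    codes = np.repeat(base, n_mark, axis=0).astype(np.int8)
    miss = rng.random(codes.shape) < 0.3
    codes[miss] = MISSING
    flip = rng.random(n_mark) < 0.2
    codes[flip] = rng.integers(0, 3, size=(int(flip.sum()), n_ind))
    positions = np.arange(n_mark) * 50 + 1
    m = matrix_from(codes, positions)
    reps = collapse_redundant(m, min_gap_bp=100)

    def compatible_all(members, j):
        for i in members:
            both = (codes[i] != MISSING) & (codes[j] != MISSING)
            if not np.all(codes[i][both] == codes[j][both]):
                return False
        return True

    runs, cur = [], [0]
    for j in range(1, n_mark):
        if compatible_all(cur, j):
            cur.append(j)
        else:
            runs.append(cur)
            cur = [j]
    runs.append(cur)
    assert [r.n_markers for r in reps] == [len(r) for r in runs]


# ------------------------------------------------------------ correction

def rep_list(codes, positions=None, contig="C1"):
    codes = np.asarray(codes, dtype=np.int8)
    if positions is None:
        positions = np.arange(len(codes)) * 1000 + 1
    m = matrix_from(codes, positions, contig)
    return collapse_redundant(m, min_gap_bp=0)


def test_isolated_flip_restored():
    codes = np.full((15, 4), A, dtype=np.int8)
    codes[7, 2] = B
    out = window_correct(rep_list(codes), window=15)
    assert out[7].codes[2] == A


def test_clean_two_segment_vector_unchanged():
    codes = np.full((30, 1), A, dtype=np.int8)
    codes[15:, 0] = H
    out = window_correct(rep_list(codes), window=15)
    assert [int(r.codes[0]) for r in out] == [A] * 15 + [H] * 15


def test_tied_window_leaves_missing_center():
    codes = np.r_[np.full((7, 1), A, dtype=np.int8),
                  np.full((1, 1), MISSING, dtype=np.int8),
                  np.full((7, 1), B, dtype=np.int8)]
    out = window_correct(rep_list(codes), window=15)
    assert out[7].codes[0] == MISSING


def test_strict_majority_imputes_missing_center():
    codes = np.full((15, 1), H, dtype=np.int8)
    codes[7, 0] = MISSING
    out = window_correct(rep_list(codes), window=15)
    assert out[7].codes[0] == H


def test_even_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        window_correct(rep_list(np.full((4, 1), A)), window=4)


def test_correction_idempotent_on_isolated_errors():
    rng = np.random.default_rng(1)
    codes = np.full((200, 6), A, dtype=np.int8)
    # isolated errors far apart (no adjacent conflicts)
    for j in range(6):
        for i in rng.choice(np.arange(5, 195, 20), size=5, replace=False):
            codes[i, j] = B
    once = window_correct(rep_list(codes))
    twice = window_correct(once)
    assert all(np.array_equal(a.codes, b.codes)
               for a, b in zip(once, twice))


def test_correction_reduces_simulated_error_rate():
    """With isolated errors at 2% the post-correction error rate drops
    below 10% of the pre-correction rate, measured against truth."""
    cfg = single_trait_config(marker_density=10.0, miscall_run_rate=0.0,
                              missing_rate=0.0, seed=9)
    truth, obs, _ = simulate_f2(cfg)
    corrupt, _ = inject_isolated_errors(obs, 0.02, seed=3)
    reps = collapse_redundant(corrupt, min_gap_bp=0)
    corrected = np.stack([r.codes for r in window_correct(reps)])
    true_codes = truth.true_matrix.codes
    pre = np.mean(corrupt.codes != true_codes)
    post = np.mean(corrected != true_codes)
    assert post < 0.1 * pre


def test_audit_records_every_change():
    codes = np.full((15, 2), A, dtype=np.int8)
    codes[7, 1] = B
    out, audit = window_correct(rep_list(codes), return_audit=True)
    assert len(audit) == 1
    assert audit.iloc[0]["old"] == "B" and audit.iloc[0]["new"] == "A"


# ------------------------------------------------------------------- bins

def test_adjacent_identical_representatives_form_one_bin():
    reps = rep_list(np.array([[A, H], [A, H]]), positions=[100, 5000])
    assert len(build_bins(reps)) == 1


def test_differing_representatives_form_two_bins():
    reps = rep_list(np.array([[A, H], [A, B]]), positions=[100, 5000])
    assert len(build_bins(reps)) == 2


def test_bin_marker_accounting():
    # 17 original markers spread over compatible representatives -> one bin
    codes = np.repeat([[A, H, B]], 17, axis=0)
    positions = np.arange(17) * 50 + 1  # all within 100 bp -> collapse first
    m = matrix_from(codes, positions)
    reps = collapse_redundant(m)
    bins = build_bins(reps)
    assert len(bins) == 1
    assert bins[0].n_markers == 17


def test_bin_counts_and_span():
    reps = rep_list(np.array([[A, H, B, MISSING], [A, MISSING, B, MISSING]]),
                    positions=[100, 900])
    b = build_bins(reps)[0]
    assert (b.start_bp, b.end_bp) == (100, 900)
    assert b.counts == (1, 1, 1, 1)


def test_counts_le_chain(small_cross):
    _, _, obs, _ = small_cross
    reps = collapse_redundant(obs)
    bins = build_bins(window_correct(reps))
    assert len(bins) <= len(reps) <= obs.n_markers
    assert sum(b.n_markers for b in bins) == obs.n_markers


# ----------------------------------------------------------------- filter

def make_bin(nA, nH, nB, nMiss=0):
    codes = np.array([A] * nA + [H] * nH + [B] * nB + [MISSING] * nMiss,
                     dtype=np.int8)
    return Bin("C1", 1, 2, 1, codes)


@pytest.mark.parametrize("counts,kept", [
    ((30, 60, 30), True),    # ideal 1:2:1 in 120 plants
    ((19, 62, 39), False),   # nA below 20
    ((39, 62, 19), False),   # nB below 20
    ((40, 39, 41), False),   # nH below 40
    ((20, 40, 20), True),    # exactly at the thresholds
])
def test_distortion_filter(counts, kept):
    bins = filter_distorted([make_bin(*counts)])
    assert (len(bins) == 1) == kept


def test_ideal_segregation_bins_rarely_filtered():
    """Clean 1:2:1 segregation survives the default filter: a large
    (10,000-plant) population's genotype fractions scaled to 120 plants
    pass in at least 99% of replicates, and direct 120-plant draws pass
    in the vast majority."""
    rng = np.random.default_rng(0)
    n_rep = 1000
    kept_scaled = kept_direct = 0
    for _ in range(n_rep):
        big = rng.multinomial(10_000, [0.25, 0.5, 0.25])
        scaled = np.round(big * 120 / 10_000).astype(int)
        kept_scaled += len(filter_distorted([make_bin(*scaled)]))
        kept_direct += len(filter_distorted(
            [make_bin(*rng.multinomial(120, [0.25, 0.5, 0.25]))]))
    assert kept_scaled / n_rep >= 0.99
    assert kept_direct / n_rep >= 0.95
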