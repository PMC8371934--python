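"""Calibration and recovery experiments on synthetic crosses.

Each function runs one validation experiment end to end with the package's
own machinery and returns plain numbers: how closely the EM recombination
estimator tracks an exhaustive likelihood grid, how much genotyping error
the sliding-window correction removes, whether the permutation threshold
holds its nominal type-I error, and how well QTL position and PVE are
recovered at the study's sample size. They are used by the test suite and
by the reproduction script, and are handy for re-validating the pipeline
after changes.
"""

from __future__ import annotations

import numpy as np

from . import binning
from .coding import MISSING
from .genmap import (_em_r, _loglik, group_bins, kosambi_cM, kosambi_inverse,
                     space_map)
from .qtlscan import call_qtls, permutation_threshold, scan_im
from .simdata import (QTLSpec, SimConfig, inject_isolated_errors,
                      simulate_annotation, simulate_f2)


def _one_trait_config(seed: int, **kw) -> SimConfig:
    defaults = dict(
        n_chromosomes=1, chrom_length_cM=100.0, marker_density=2.0,
        qtl_spec={"L": [QTLSpec(1, 45.0, 1.0, 0.0, 0.40)]},
        trait_corr=np.array([[1.0]]), trait_means={"L": 0.0},
        trait_sds={"L": 1.0}, seed=seed)
    defaults.update(kw)
    return SimConfig(**defaults)


def em_vs_grid_max_deviation(n_tables: int = 1000, seed: int = 0,
                             grid_step: float = 1e-4) -> float:
    """Largest |r_EM - r_grid| over random 3x3 F2 genotype tables, where
    the oracle is a dense grid search of the likelihood."""
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
    worst = 0.0
    for _ in range(n_tables):
        counts = rng.integers(0, 25, size=(3, 3)).astype(float)
        if counts.sum() < 2:
            continue
        r_em = float(_em_r(counts))
        r_grid = float(grid[np.argmax(_loglik(counts, grid))])
        worst = max(worst, abs(r_em - r_grid))
    return worst


def kosambi_roundtrip_max_error() -> float:
    r = np.arange(0.01, 0.46, 0.01)
    return float(np.max(np.abs(kosambi_inverse(kosambi_cM(r)) - r)))


def window_correction_reduction(n_individuals: int = 120,
                                n_markers: int = 2000,
                                error_rate: float = 0.02,
                                seed: int = 0) -> dict[str, float]:
    """Fraction of injected isolated errors removed by the 15-marker
    sliding-window pass on a clean simulated cross."""
    density = n_markers / 200.0  # two 100 cM chromosomes
    cfg = _one_trait_config(seed, n_chromosomes=2, marker_density=density,
                            n_individuals=n_individuals,
                            miscall_run_rate=0.0, missing_rate=0.0)
    truth, obs, _ = simulate_f2(cfg)
    corrupt, _ = inject_isolated_errors(obs, error_rate, seed=seed + 1)
    reps = binning.collapse_redundant(corrupt, min_gap_bp=0)
    corrected = np.stack([r.codes for r in binning.window_correct(reps)])
    true_codes = truth.true_matrix.codes
    pre = float(np.mean(corrupt.codes != true_codes))
    post = float(np.mean(corrected != true_codes))
    return {"pre_error_rate": pre, "post_error_rate": post,
            "reduction": 1.0 - post / pre, "n_markers": obs.n_markers}


def _build_map(obs, min_group_size: int = 10):
    bins = binning.make_bin_map(obs)
    return space_map(group_bins(bins, min_group_size=min_group_size))


def im_type1_error(n_reps: int = 200, n_perm: int = 200,
                   alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Empirical genome-wide type-I error of the IM permutation threshold
    under the null: one fixed noisy map, fresh null phenotypes per
    replicate, per-replicate thresholds from ``n_perm`` permutations."""
    import pandas as pd

    cfg = _one_trait_config(seed, n_chromosomes=2, marker_density=1.0)
    _, obs, _ = simulate_f2(cfg)
    gmap = _build_map(obs)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for rep in range(n_reps):
        y = rng.standard_normal(cfg.n_individuals)
        pheno = pd.DataFrame({"y": y}, index=obs.individuals)
        scan = scan_im(gmap, pheno, "y", individuals=obs.individuals)
        thr = permutation_threshold(gmap, pheno, "y", n_perm=n_perm,
                                    alpha=alpha,
                                    seed=int(rng.integers(2 ** 31)),
                                    individuals=obs.individuals)
        hits += scan.max_lod > thr
    return {"type1_error": hits / n_reps, "n_reps": n_reps,
            "n_perm": n_perm}


def qtl_recovery(n_reps: int = 200, pve: float = 0.40, n_perm: int = 200,
                 seed: int = 0) -> dict[str, float]:
    """Peak-position and PVE recovery for a single simulated QTL at the
    study's sample size (n = 120), run through the full noisy-genotype ->
    bin map -> linkage map -> IM scan chain.

    The true position is expressed in map coordinates as the spaced cM of
    the bin covering the QTL's physical location, since the estimated map
    has its own (slightly compressed) scale.
    """
    import pandas as pd

    peak_errors, pves = [], []
    detected = 0
    rng = np.random.default_rng(seed)
    for rep in range(n_reps):
        cfg = _one_trait_config(int(rng.integers(2 ** 31)),
                                qtl_spec={"L": [QTLSpec(1, 45.0, 1.0, 0.0,
                                                        pve)]})
        _, obs, pheno = simulate_f2(cfg)
        gmap = _build_map(obs)
        grp = gmap.groups[0]
        qtl_bp = 45.0 * cfg.bp_per_cM
        dist = [0 if b.start_bp <= qtl_bp <= b.end_bp
                else min(abs(b.start_bp - qtl_bp), abs(b.end_bp - qtl_bp))
                for b in grp.bins]
        true_cM = grp.cM_positions[int(np.argmin(dist))]
        scan = scan_im(gmap, pheno, "L", individuals=obs.individuals)
        scan.threshold = permutation_threshold(
            gmap, pheno, "L", n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)), individuals=obs.individuals)
        calls = call_qtls(scan, gmap, pheno, individuals=obs.individuals)
        if not calls:
            continue
        detected += 1
        best = max(calls, key=lambda c: c.peak_lod)
        peak_errors.append(best.peak_cM - true_cM)
        pves.append(best.pve)
    return {
        "detection_rate": detected / n_reps,
        "median_abs_peak_error_cM": float(np.median(np.abs(peak_errors))),
        "median_pve": float(np.median(pves)),
        "n_reps": n_reps,
    }


def map_length_recovery(n_reps: int = 5, seed: int = 0) -> dict[str, float]:
    """Mean estimated length of a simulated 100 cM chromosome (dense
    markers, default noise) after binning and Kosambi spacing."""
    lengths = []
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cfg = _one_trait_config(int(rng.integers(2 ** 31)),
                                marker_density=5.0)
        _, obs, _ = simulate_f2(cfg)
        gmap = _build_map(obs)
        lengths.append(gmap.groups[0].length_cM)
    return {"mean_length_cM": float(np.mean(lengths)),
            "true_length_cM": 100.0, "n_reps": n_reps}


def candidate_screen_recovery(seed: int = 0, n_planted: int = 5,
                              n_decoys: int = 20,
                              n_genes: int = 60) -> dict[str, int]:
    """Run the full candidate screen on an annotation fixture with planted
    candidates and single-violation decoys; count recovered and spurious
    candidates."""
    from . import candidates as cand
    from .intervals import PhysicalSegment

    cfg = SimConfig(seed=seed)
    genes, variants, deg = simulate_annotation(
        cfg, n_genes=n_genes, n_planted_candidates=n_planted,
        n_decoys=n_decoys)
    segments = [PhysicalSegment(cfg.contig_name(c), 1, 10 ** 9)
                for c in range(1, cfg.n_chromosomes + 1)]
    models = [cand.GeneModel(g.gene_id, g.contig, g.start, g.end, g.strand,
                             g.exons) for g in genes]
    in_seg = cand.genes_in_segments(models, segments)
    coseg = cand.coseg_screen(variants)
    high = coseg[coseg["impact"].str.lower() == "high"]
    flags = cand.deg_flags(deg)
    evidence = cand.screen_candidates(in_seg, high, flags)
    passing = {e.gene_id for e in evidence if e.passes}
    planted = {g.gene_id for g in genes if g.role == "candidate"}
    return {"n_planted": len(planted),
            "n_recovered": len(passing & planted),
            "n_false": len(passing - planted)}
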