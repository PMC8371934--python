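"""QTL scanning: conditional genotype probabilities, IM/CIM profiles,
permutation thresholds, cofactor selection and QTL calling."""

import numpy as np
import pandas as pd
import pytest

from conftest import single_trait_config
from sesaqtl.binning import Bin
from sesaqtl.coding import A, B, H, MISSING
from sesaqtl.genmap import GeneticMap, LinkageGroup, kosambi_inverse
from sesaqtl.qtlscan import (QTLScanModel, call_qtls, genotype_probs_f2,
                             permutation_threshold, scan_cim, scan_im,
                             select_cofactors)
from sesaqtl.simdata import simulate_f2


# ------------------------------------------------- probability oracle

def brute_force_probs(code_l, code_r, r1, r2):
    """Enumerate the 16 two-locus gamete combinations per parental pair
    to get P(QTL genotype | flanks) independently of the implementation."""
    def gamete(hl, hq, hr):
        p = 0.5
        p *= r1 if hq != hl else 1 - r1
        p *= r2 if hr != hq else 1 - r2
        return p

    probs = np.zeros(3)
    total = 0.0
    for g1 in np.ndindex(2, 2, 2):
        for g2 in np.ndindex(2, 2, 2):
            gl, gq, gr = (g1[0] + g2[0], g1[1] + g2[1], g1[2] + g2[2])
            w = gamete(*g1) * gamete(*g2)
            if (code_l in (gl, None)) and (code_r in (gr, None)):
                probs[gq] += w
                total += w
    return probs / total


def test_probability_rows_sum_to_one():
    codes_l = np.array([A, H, B, MISSING], np.int8)
    codes_r = np.array([B, MISSING, A, H], np.int8)
    p = genotype_probs_f2(codes_l, codes_r, 3.7, 8.2)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_zero_distance_gives_indicator():
    codes = np.array([A, H, B], np.int8)
    p = genotype_probs_f2(codes, codes, 0.0, 5.0)
    assert np.allclose(p, np.eye(3), atol=1e-9)


def test_probs_match_enumeration_oracle():
    r1, r2 = 0.12, 0.07
    d1 = 25 * np.log((1 + 2 * r1) / (1 - 2 * r1))
    d2 = 25 * np.log((1 + 2 * r2) / (1 - 2 * r2))
    for cl in (A, H, B, None):
        for cr in (A, H, B, None):
            codes_l = np.array([MISSING if cl is None else cl], np.int8)
            codes_r = np.array([MISSING if cr is None else cr], np.int8)
            got = genotype_probs_f2(codes_l, codes_r, d1, d2)[0]
            want = brute_force_probs(cl, cr, r1, r2)
            assert np.allclose(got, want, atol=1e-9), (cl, cr)


def test_opposite_homozygous_flanks_favor_heterozygote():
    p = genotype_probs_f2(np.array([A], np.int8), np.array([B], np.int8),
                          10.0, 10.0)[0]
    assert p[H] == max(p)


def test_position_outside_interval_rejected():
    with pytest.raises(ValueError):
        genotype_probs_f2(np.array([A], np.int8), np.array([B], np.int8),
                          -1.0, 5.0)


# ------------------------------------------------------- scan fixtures

def toy_map(n_bins=11, n_ind=120, seed=0, spacing_cM=10.0):
    """Clean single-group map built from a simulated chromosome's true
    codes at evenly spaced bins."""
    rng = np.random.default_rng(seed)
    # simulate haplotypes marker by marker with r per interval
    r = kosambi_inverse(spacing_cM)
    h = np.empty((n_bins, 2, n_ind), np.int8)
    h[0] = rng.integers(0, 2, (2, n_ind))
    for i in range(1, n_bins):
        flip = rng.random((2, n_ind)) < r
        h[i] = np.where(flip, 1 - h[i - 1], h[i - 1])
    codes = h.sum(axis=1).astype(np.int8)
    bins = [Bin("C1", 1 + i * 1000, 1 + i * 1000, 1, codes[i])
            for i in range(n_bins)]
    group = LinkageGroup(1, bins,
                         cM_positions=[i * spacing_cM for i in range(n_bins)])
    return GeneticMap([group]), codes


def test_noiseless_additive_phenotype_peaks_at_bin():
    gmap, codes = toy_map(seed=1)
    y = codes[5].astype(float) - 1.0
    pheno = pd.DataFrame({"L": y})
    scan = scan_im(gmap, pheno, "L", step=1.0)
    peak = scan.profile.loc[scan.profile["lod"].idxmax()]
    assert peak["cM"] == pytest.approx(50.0, abs=1.0)
    scan.threshold = 3.0
    calls = call_qtls(scan, gmap, pheno)
    assert len(calls) == 1
    assert calls[0].pve == pytest.approx(1.0, abs=1e-9)


def test_lod_at_bins_equals_single_marker_regression():
    """On the bin grid the interval-mapping LOD equals the plain two-
    predictor marker regression LOD."""
    gmap, codes = toy_map(seed=2)
    rng = np.random.default_rng(3)
    y = codes[4] - 1.0 + 0.8 * rng.standard_normal(codes.shape[1])
    pheno = pd.DataFrame({"L": y})
    scan = scan_im(gmap, pheno, "L", step=10.0)  # grid falls on the bins
    n = codes.shape[1]
    for i, row in scan.profile.iterrows():
        k = int(row["cM"] / 10.0)
        X = np.column_stack([np.ones(n), codes[k] - 1.0,
                             (codes[k] == H).astype(float)])
        beta, rss1, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(rss1[0])
        rss0 = float(((y - y.mean()) ** 2).sum())
        lod = (n / 2) * np.log10(rss0 / rss1)
        assert row["lod"] == pytest.approx(lod, abs=1e-9)


def test_lod_invariant_to_affine_phenotype_transform():
    gmap, codes = toy_map(seed=4)
    rng = np.random.default_rng(5)
    y = codes[2] - 1.0 + rng.standard_normal(codes.shape[1])
    s1 = scan_im(gmap, pd.DataFrame({"L": y}), "L")
    s2 = scan_im(gmap, pd.DataFrame({"L": 3.5 * y - 40.0}), "L")
    assert np.allclose(s1.profile["lod"], s2.profile["lod"], atol=1e-9)


def test_too_few_phenotyped_individuals():
    gmap, _ = toy_map(n_ind=8)
    with pytest.raises(ValueError, match="10 phenotyped"):
        scan_im(gmap, pd.DataFrame({"L": np.zeros(8)}), "L")


# ------------------------------------------------------- permutations

def test_threshold_deterministic_given_seed():
    gmap, codes = toy_map(seed=6)
    pheno = pd.DataFrame({"L": np.random.default_rng(0).standard_normal(120)})
    t1 = permutation_threshold(gmap, pheno, "L", n_perm=100, seed=11)
    t2 = permutation_threshold(gmap, pheno, "L", n_perm=100, seed=11)
    assert t1 == t2


def test_alpha_one_gives_minimum_of_maxima():
    gmap, codes = toy_map(seed=6)
    pheno = pd.DataFrame({"L": np.random.default_rng(0).standard_normal(120)})
    with pytest.warns(UserWarning):
        t = permutation_threshold(gmap, pheno, "L", n_perm=50, alpha=1.0,
                                  seed=1)
    with pytest.warns(UserWarning):
        t05 = permutation_threshold(gmap, pheno, "L", n_perm=50, alpha=0.05,
                                    seed=1)
    assert t <= t05


# ---------------------------------------------------------- cofactors

def test_null_phenotype_selects_no_cofactors():
    gmap, _ = toy_map(seed=7)
    pheno = pd.DataFrame({"L": np.random.default_rng(1).standard_normal(120)})
    assert len(select_cofactors(gmap, pheno, "L", max_cofactors=5)) <= 1


def test_strong_qtl_bin_selected_first():
    gmap, codes = toy_map(seed=8)
    rng = np.random.default_rng(2)
    y = 2.0 * (codes[6] - 1.0) + 0.5 * rng.standard_normal(codes.shape[1])
    chosen = select_cofactors(gmap, pd.DataFrame({"L": y}), "L",
                              max_cofactors=3)
    assert chosen[0] == (1, 6)


def test_cim_without_cofactors_equals_im():
    gmap, codes = toy_map(seed=9)
    rng = np.random.default_rng(3)
    y = codes[3] - 1.0 + rng.standard_normal(codes.shape[1])
    pheno = pd.DataFrame({"L": y})
    im = scan_im(gmap, pheno, "L", step=2.0)
    cim = scan_cim(gmap, pheno, "L", cofactors=[], step=2.0)
    assert np.allclose(im.profile["lod"], cim.profile["lod"], atol=1e-9)


def test_cofactor_excluded_inside_window():
    """A cofactor within the exclusion window must not appear in the
    design at that position: the CIM LOD there equals the IM LOD."""
    gmap, codes = toy_map(seed=10)
    rng = np.random.default_rng(4)
    y = codes[5] - 1.0 + rng.standard_normal(codes.shape[1])
    pheno = pd.DataFrame({"L": y})
    cim = scan_cim(gmap, pheno, "L", cofactors=[(1, 5)], step=1.0,
                   window=10.0)
    im = scan_im(gmap, pheno, "L", step=1.0)
    at_peak_cim = cim.profile.set_index("cM").loc[50.0, "lod"]
    at_peak_im = im.profile.set_index("cM").loc[50.0, "lod"]
    assert at_peak_cim == pytest.approx(at_peak_im, abs=1e-9)
    # far from the cofactor the designs differ
    far_cim = cim.profile.set_index("cM").loc[90.0, "lod"]
    far_im = im.profile.set_index("cM").loc[90.0, "lod"]
    assert far_cim != pytest.approx(far_im, abs=1e-9)


def test_linked_qtls_separated_by_cim():
    """Two QTLs 40 cM apart: CIM resolves both peaks above threshold in
    most replicates."""
    from sesaqtl.simdata import QTLSpec

    hits = 0
    n_rep = 25
    for seed in range(n_rep):
        cfg = single_trait_config(
            marker_density=2.0, seed=seed + 50,
            qtl_spec={"L": [QTLSpec(1, 30.0, 1.0, 0.0, 0.30),
                            QTLSpec(1, 70.0, 1.0, 0.0, 0.30)]})
        _, obs, pheno = simulate_f2(cfg)
        from sesaqtl import binning, genmap
        bins = binning.make_bin_map(obs)
        gmap = genmap.space_map(genmap.group_bins(bins, min_group_size=10))
        model = QTLScanModel(gmap, pheno, "L", method="cim",
                             individuals=obs.individuals)
        res = model.fit(n_perm=100, seed=seed)
        peaks = sorted(c.peak_cM for c in res.qtls)
        if len(peaks) >= 2 and peaks[-1] - peaks[0] > 20:
            hits += 1
    assert hits / n_rep >= 0.8


# ------------------------------------------------------------- calling

def test_no_super_threshold_region_yields_no_calls():
    gmap, _ = toy_map(seed=11)
    pheno = pd.DataFrame({"L": np.random.default_rng(5).standard_normal(120)})
    scan = scan_im(gmap, pheno, "L")
    scan.threshold = 1e6
    assert call_qtls(scan, gmap, pheno) == []


def test_call_without_threshold_rejected():
    gmap, _ = toy_map(seed=11)
    pheno = pd.DataFrame({"L": np.random.default_rng(5).standard_normal(120)})
    scan = scan_im(gmap, pheno, "L")
    with pytest.raises(ValueError, match="threshold"):
        call_qtls(scan, gmap, pheno)


def test_model_facade_summary_and_plot(small_cross, small_map):
    import matplotlib
    matplotlib.use("Agg")

    _, _, obs, pheno = small_cross
    model = QTLScanModel(small_map, pheno, "L", method="im",
                         individuals=obs.individuals)
    res = model.fit(n_perm=100, seed=0)
    text = res.summary()
    assert "trait L" in text and "threshold" in text
    assert res.threshold > 0
    assert len(res.qtls) >= 1  # the planted PVE-0.40 QTL
    ax = res.plot()
    assert ax.get_ylabel() == "LOD"
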