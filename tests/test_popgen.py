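"""Diversity indices, F-statistics, AMOVA, distances, trees, PCoA."""

import math

import numpy as np
import pandas as pd
import pytest
import skbio

from ilpkit import popgen, synthetic_data as sd
from ilpkit.popgen import BandMatrix, GenotypeTable


def _geno(rows, pops=None, loci=("L1",)):
    """rows: list of per-individual genotype tuples (one per locus)."""
    idx = [f"i{k}" for k in range(len(rows))]
    df = pd.DataFrame(rows, index=idx, columns=list(loci))
    pops = pops or ["p1"] * len(rows)
    return GenotypeTable(df, pd.Series(pops, index=idx))


# ---------------------------------------------------------------- bands ----

def test_band_scoring_rules():
    cols = pd.MultiIndex.from_tuples(
        [("L1", 180), ("L1", 200), ("L1", 220)])
    df = pd.DataFrame(
        [[1, 0, 0], [1, 1, 0], [1, 1, 1], [0, 0, 0]],
        index=["a", "b", "c", "d"], columns=cols)
    bm = BandMatrix(df, pd.Series(["p"] * 4, index=df.index))
    g = popgen.bands_to_genotypes(bm)
    assert g.df.at["a", "L1"] == (180, 180)
    assert g.df.at["b", "L1"] == (180, 200)
    assert g.df.at["c", "L1"] is None   # >2 bands is ambiguous
    assert g.df.at["d", "L1"] is None


def test_band_matrix_validates_entries():
    cols = pd.MultiIndex.from_tuples([("L1", 180)])
    with pytest.raises(ValueError):
        BandMatrix(pd.DataFrame([[2]], index=["a"], columns=cols),
                   pd.Series(["p"], index=["a"]))


def test_band_matrix_csv_round_trip(tmp_path):
    genos, _ = sd.simulate_population_genotypes(5, 2, 8, 0.1, seed=3)
    bm = sd.genotypes_to_bands(genos)
    path = tmp_path / "bands.csv"
    bm.to_csv(str(path))
    back = BandMatrix.from_csv(str(path))
    pd.testing.assert_frame_equal(back.df, bm.df, check_names=False)
    assert list(back.populations) == list(bm.populations)


# ---------------------------------------------------------- frequencies ----

def test_allele_counting():
    g = _geno([((1, 1),), ((1, 2),)])
    f = popgen.allele_frequencies(g)["L1"]
    assert f[1] == 0.75 and f[2] == 0.25
    g2 = _geno([(None,), (None,)])
    assert popgen.allele_frequencies(g2) == {}


def test_frequency_estimates_within_three_binomial_se():
    genos, truth = sd.simulate_population_genotypes(
        10, 1, 500, 0.0, seed=13)
    est = popgen.allele_frequencies(genos)
    for locus, p_true in truth.ancestral_freqs.items():
        p_hat = est[locus].reindex(p_true.index, fill_value=0.0)
        se = np.sqrt(p_true * (1 - p_true) / (2 * 500))
        assert (np.abs(p_hat - p_true) <= 3 * se + 1e-12).all()


# ------------------------------------------------------------- diversity ----

def test_locus_diversity_closed_forms():
    g = _geno([((1, 1),), ((1, 2),), ((2, 2),), ((1, 2),)])
    d = popgen.locus_diversity(g, "L1", levene=False)
    assert d.na == 2
    assert d.ne == pytest.approx(2.0)
    assert d.shannon_i == pytest.approx(math.log(2), abs=1e-4)
    assert d.h == pytest.approx(0.5)
    assert d.pic == pytest.approx(0.375)
    assert d.obs_ho == pytest.approx(0.5)
    assert d.obs_ho + d.obs_he == pytest.approx(1.0)
    assert d.exp_ho + d.exp_he == pytest.approx(1.0)


def test_monomorphic_locus_is_not_an_error():
    g = _geno([((1, 1),), ((1, 1),)])
    d = popgen.locus_diversity(g, "L1")
    assert (d.na, d.ne, d.shannon_i, d.h, d.pic) == (1, 1.0, 0.0, 0.0, 0.0)


def test_levene_correction_shifts_expected_heterozygosity():
    g = _geno([((1, 2),)] * 4)
    plain = popgen.locus_diversity(g, "L1", levene=False)
    lev = popgen.locus_diversity(g, "L1", levene=True)
    assert plain.exp_he == pytest.approx(0.5)
    assert lev.exp_he == pytest.approx(0.5 * 8 / 7)
    assert lev.h == plain.h  # H itself is uncorrected


def test_pic_and_h_bounds_on_random_frequency_vectors():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        k = int(rng.integers(2, 8))
        p = rng.dirichlet(np.ones(k))
        h = 1 - np.sum(p ** 2)
        pic = popgen.pic_from_frequencies(p)
        assert pic <= h + 1e-12
        assert h <= 1 - 1 / k + 1e-12


def test_population_diversity_table():
    rows = [((1, 1), (1, 2)), ((1, 1), (1, 2)), ((1, 1), (2, 2))]
    g = _geno(rows, loci=("L1", "L2"))
    out = popgen.population_diversity(g)
    assert out.loc["p1", "PPB_pct"] == pytest.approx(50.0)  # L1 monomorphic
    # mean H equals the arithmetic mean of per-locus H
    h1 = popgen.locus_diversity(g, "L1").h
    h2 = popgen.locus_diversity(g, "L2").h
    assert out.loc["p1", "H"] == pytest.approx((h1 + h2) / 2)
    with pytest.raises(ValueError):
        g.population("nope")


# ----------------------------------------------------------- F-statistics ----

def test_fst_zero_for_identical_populations():
    rows = [((1, 2),), ((1, 1),), ((2, 2),), ((1, 2),)]
    g = _geno(rows * 2, pops=["p1"] * 4 + ["p2"] * 4)
    fs = popgen.f_statistics(g)
    assert fs.fst == pytest.approx(0.0, abs=1e-12)


def test_fixed_populations_give_complete_differentiation():
    g = _geno([((1, 1),)] * 3 + [((2, 2),)] * 3,
              pops=["p1"] * 3 + ["p2"] * 3)
    fs = popgen.f_statistics(g)
    assert fs.fst == pytest.approx(1.0)
    assert fs.fit == pytest.approx(1.0)
    assert fs.nm is None or fs.nm == 0.0


def test_balding_nichols_fst_recovery():
    """Corrected multi-locus Fst recovers the simulation target 0.05
    within +-0.02 (20 loci, 3 populations x 200)."""
    genos, _ = sd.simulate_population_genotypes(
        20, 3, 200, target_fst=0.05, seed=7)
    fs = popgen.f_statistics(genos)
    est = popgen.fst_finite_demes_correction(fs.fst, 3)
    assert abs(est - 0.05) <= 0.02


def test_nm_matches_fst_island_model_relation():
    genos, _ = sd.simulate_population_genotypes(10, 3, 80, 0.1, seed=5)
    fs = popgen.f_statistics(genos)
    assert fs.nm == pytest.approx(0.25 * (1 - fs.fst) / fs.fst)


# ------------------------------------------------------------------ AMOVA ----

def test_amova_partition_identities():
    genos, _ = sd.simulate_population_genotypes(
        12, 3, [20, 15, 25], 0.08, seed=19)
    bm = sd.genotypes_to_bands(genos)
    res = popgen.amova(bm, n_permutations=99, seed=1)
    assert (res.df_among, res.df_within) == (2, 57)
    assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)
    assert res.pmv_among + res.pmv_within == pytest.approx(100.0)
    assert 0 < res.p_value <= 1


def test_amova_study_layout_degrees_of_freedom():
    genos, _ = sd.simulate_population_genotypes(
        10, 3, [55, 30, 91], 0.05, seed=23)
    res = popgen.amova(sd.genotypes_to_bands(genos))
    assert (res.df_among, res.df_within) == (2, 173)


def test_duplicated_populations_have_zero_among_component():
    genos, _ = sd.simulate_population_genotypes(8, 1, 12, 0.0, seed=2)
    bm = sd.genotypes_to_bands(genos)
    df2 = pd.concat([bm.df, bm.df.set_axis([f"{i}_b" for i in bm.df.index])])
    pops = pd.Series(["pA"] * 12 + ["pB"] * 12, index=df2.index)
    res = popgen.amova(df2, pops)
    assert res.sigma2_among <= 0
    assert res.pmv_among == 0.0


def test_pmv_from_printed_variance_components():
    pmv = popgen.variance_components_to_pmv([1.35, 19.76])
    assert round(pmv[0], 2) == 6.40
    assert round(pmv[1], 2) == 93.60
    assert popgen.variance_components_to_pmv([-0.5, 2.0])[0] == 0.0


def test_amova_rejects_degenerate_layouts():
    genos, _ = sd.simulate_population_genotypes(5, 1, 6, 0.0, seed=3)
    bm = sd.genotypes_to_bands(genos)
    with pytest.raises(ValueError):
        popgen.amova(bm)  # single population


# ----------------------------------------------------------- Nei distance ----

def test_nei_identity_of_identical_populations():
    f = {"L1": pd.Series({1: 0.5, 2: 0.5}), "L2": pd.Series({1: 1.0})}
    s, d = popgen.nei_identity_distance(f, f)
    assert s == pytest.approx(1.0)
    assert d == pytest.approx(0.0)


def test_nei_hand_computed_two_locus_example():
    fa = {"L1": pd.Series({1: 0.5, 2: 0.5}), "L2": pd.Series({1: 1.0})}
    fb = {"L1": pd.Series({1: 0.8, 2: 0.2}), "L2": pd.Series({1: 1.0})}
    s, d = popgen.nei_identity_distance(fa, fb)
    # Jx = (0.5+1)/2, Jy = (0.68+1)/2, Jxy = (0.5+1)/2
    expect_s = 0.75 / math.sqrt(0.75 * 0.84)
    assert s == pytest.approx(expect_s)
    assert d == pytest.approx(-math.log(expect_s))


def test_printed_similarity_implies_printed_distance():
    assert round(-math.log(0.94), 2) == 0.06


# ------------------------------------------------------------------ trees ----

ADDITIVE = pd.DataFrame(
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
    index=list("ABCD"), columns=list("ABCD"), dtype=float)


def _tip_distances(tree, labels):
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = tree.find(a).distance(tree.find(b))
            out.loc[a, b] = out.loc[b, a] = d
    return out


def test_nj_recovers_additive_four_taxon_tree_exactly():
    tree = popgen.nj_tree(ADDITIVE)
    got = _tip_distances(tree, list("ABCD"))
    assert np.allclose(got.to_numpy(), ADDITIVE.to_numpy(), atol=1e-9)
    # split AB|CD: removing the internal edge separates {A,B} from {C,D}
    lca = tree.lca(["A", "B"])
    assert {t.name for t in lca.tips()} in ({"A", "B"}, {"C", "D"})


def test_nj_three_taxa_solves_three_point_equations():
    dm = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0]],
                      index=list("XYZ"), columns=list("XYZ"), dtype=float)
    tree = popgen.nj_tree(dm)
    got = _tip_distances(tree, list("XYZ"))
    assert np.allclose(got.to_numpy(), dm.to_numpy(), atol=1e-9)


def test_nj_topology_invariant_to_label_order():
    perm = ["C", "A", "D", "B"]
    t1 = popgen.nj_tree(ADDITIVE)
    t2 = popgen.nj_tree(ADDITIVE.loc[perm, perm])
    d1 = _tip_distances(t1, list("ABCD"))
    d2 = _tip_distances(t2, list("ABCD"))
    assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)


def test_nj_rejects_asymmetric_input():
    bad = ADDITIVE.copy()
    bad.iloc[0, 1] = 99
    with pytest.raises(ValueError):
        popgen.nj_tree(bad)


def test_upgma_cut_at_similarity_threshold():
    sim = pd.DataFrame(
        [[1, 0.99, 0.90, 0.90], [0.99, 1, 0.90, 0.90],
         [0.90, 0.90, 1, 0.99], [0.90, 0.90, 0.99, 1.0]],
        index=list("wxyz"), columns=list("wxyz"), dtype=float)
    _, clusters = popgen.upgma_tree(sim, cut_threshold=0.924, is_similarity=True)
    assert clusters["w"] == clusters["x"]
    assert clusters["y"] == clusters["z"]
    assert clusters["w"] != clusters["y"]
    _, singletons = popgen.upgma_tree(sim, cut_threshold=1.0, is_similarity=True)
    assert singletons.nunique() == 4


def test_upgma_reproduces_ultrametric_input_exactly():
    # ultrametric from a clock tree: ((a:1,b:1):2,(c:2,d:2):1)
    u = pd.DataFrame(
        [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
        index=list("abcd"), columns=list("abcd"), dtype=float)
    nwk, _ = popgen.upgma_tree(u)
    tree = skbio.TreeNode.read([nwk])
    got = _tip_distances(tree, list("abcd"))
    assert np.allclose(got.to_numpy(), u.to_numpy(), atol=1e-9)


# ------------------------------------------------------------------- PCoA ----

def test_pcoa_reconstructs_planar_configuration():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(5, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    res = popgen.pcoa(pd.DataFrame(d, index=list("abcde"), columns=list("abcde")))
    coords = res.coordinates.to_numpy()[:, :2]
    d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    assert np.abs(d - d2).max() <= 1e-8
    assert res.pct_variance.sum() == pytest.approx(100.0)


def test_pcoa_identical_individuals_coincide():
    d = pd.DataFrame(
        [[0, 0, 1], [0, 0, 1], [1, 1, 0]],
        index=list("abc"), columns=list("abc"), dtype=float)
    res = popgen.pcoa(d)
    assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"])


def test_pcoa_zero_matrix_gives_zero_coordinates():
    d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
    res = popgen.pcoa(d)
    assert np.allclose(res.coordinates.to_numpy(), 0.0)


# ----------------------------------------------------------- band distance ----

def test_simple_matching_and_jaccard_band_distances():
    df = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0]],
                      index=list("abc"))
    d_sm = popgen.band_distance_matrix(df, "simple_matching")
    assert d_sm.loc["a", "c"] == 0.0
    assert d_sm.loc["a", "b"] == pytest.approx(0.5)
    d_j = popgen.band_distance_matrix(df, "jaccard")
    assert d_j.loc["a", "b"] == pytest.approx(1 - 1 / 3)
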