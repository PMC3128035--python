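"""Unit and property tests for the eight statistics and the rank rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_design, make_log2_matrix, random_instance
from degrank.errors import DataError, DegenerateInputError
from degrank.ranking import (
    ASCENDING,
    DESCENDING_ABS,
    METHODS,
    ClassDesign,
    ScoreTable,
    ad_statistic,
    compute_statistic,
    fc_statistic,
    ibm_t,
    moderated_t,
    rank_genes,
    rank_products,
    sam_t,
    shrinkage_t,
    wad_statistic,
)


class TestAD:
    def test_constant_replicates(self):
        mat = make_log2_matrix([[4, 4, 6, 6]])
        assert ad_statistic(mat, make_design(mat)).scores.iloc[0] == pytest.approx(2.0)

    def test_symmetric_classes_zero(self):
        mat = make_log2_matrix([[3, 5, 3, 5]])
        assert ad_statistic(mat, make_design(mat)).scores.iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        mat = make_log2_matrix([[1, 3, 5, 5]])
        assert ad_statistic(mat, make_design(mat)).scores.iloc[0] == pytest.approx(3.0)

    def test_ordering_convention(self):
        mat = make_log2_matrix([[1, 3, 5, 5]])
        assert ad_statistic(mat, make_design(mat)).ordering == DESCENDING_ABS


class TestFC:
    def test_constant_replicates_equals_ad(self):
        mat = make_log2_matrix([[4, 4, 6, 6]])
        assert fc_statistic(mat, make_design(mat)).scores.iloc[0] == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        # class1 log2 (1,3) -> natural mean (2+8)/2 = 5; class2 (5,5) -> 32
        mat = make_log2_matrix([[1, 3, 5, 5]])
        expected = np.log2(32 / 5)
        assert fc_statistic(mat, make_design(mat)).scores.iloc[0] == pytest.approx(expected)

    def test_replicate_permutation_invariant(self):
        mat1 = make_log2_matrix([[1, 3, 5, 7]])
        mat2 = make_log2_matrix([[3, 1, 7, 5]])
        s1 = fc_statistic(mat1, make_design(mat1)).scores.iloc[0]
        s2 = fc_statistic(mat2, make_design(mat2)).scores.iloc[0]
        assert s1 == pytest.approx(s2)


class TestWAD:
    def test_min_max_weights(self):
        # three probes with mean intensities 2, 5, 8 and AD 1 each
        mat = make_log2_matrix(
            [[1.5, 1.5, 2.5, 2.5], [4.5, 4.5, 5.5, 5.5], [7.5, 7.5, 8.5, 8.5]]
        )
        wad = wad_statistic(mat, make_design(mat))
        assert wad.scores.to_numpy() == pytest.approx([0.0, 0.5, 1.0])
        assert wad.aux["weight"].to_numpy() == pytest.approx([0.0, 0.5, 1.0])

    def test_max_intensity_probe_keeps_ad(self):
        mat = make_log2_matrix([[1, 1, 2, 2], [8, 8, 11, 11]])
        wad = wad_statistic(mat, make_design(mat))
        ad = ad_statistic(mat, make_design(mat))
        assert wad.scores.iloc[1] == pytest.approx(ad.scores.iloc[1])

    def test_min_intensity_probe_is_zero(self):
        mat = make_log2_matrix([[1, 1, 3, 3], [8, 8, 9, 9]])
        assert wad_statistic(mat, make_design(mat)).scores.iloc[0] == 0.0

    def test_flat_intensity_degenerate(self):
        mat = make_log2_matrix([[5, 5, 5, 5], [4, 6, 4, 6]])
        # both probes have mean 5
        with pytest.raises(DegenerateInputError):
            wad_statistic(mat, make_design(mat))


class TestRankProducts:
    def test_single_pair_by_hand(self):
        # differences (+3, +1, -2): up-ranks (1,2,3), down-ranks (3,2,1)
        mat = make_log2_matrix([[0, 3], [0, 1], [0, -2]], ["A", "B"])
        rp = rank_products(mat, make_design(mat))
        assert rp.aux["rp_up"].to_numpy() == pytest.approx([1, 2, 3])
        assert rp.aux["rp_down"].to_numpy() == pytest.approx([3, 2, 1])
        assert rp.scores.to_numpy() == pytest.approx([1, 2, 1])
        assert rp.ordering == ASCENDING

    def test_always_most_up_gets_one(self, rng):
        x = rng.normal(5, 1, size=(20, 8))
        x[0, 4:] += 10  # gene 0 most up-regulated in every pair
        mat = make_log2_matrix(x)
        rp = rank_products(mat, make_design(mat))
        assert rp.scores.iloc[0] == pytest.approx(1.0)

    def test_net_below_both_components(self, rng):
        mat, design = random_instance(rng, m=30)
        rp = rank_products(mat, design)
        assert (rp.scores <= rp.aux["rp_up"] + 1e-12).all()
        assert (rp.scores <= rp.aux["rp_down"] + 1e-12).all()


class TestModeratedT:
    def test_equal_variances_rank_like_ad(self, rng):
        base = rng.uniform(4, 10, size=(40, 1))
        noise = rng.normal(0, 1, size=(40, 8))
        # force identical sample variance by reusing one noise pattern
        x = base + noise[0]
        mat = make_log2_matrix(x)
        t = moderated_t(mat, make_design(mat))
        ad = ad_statistic(mat, make_design(mat))
        assert np.argsort(-t.scores.abs().to_numpy()) == pytest.approx(
            np.argsort(-ad.scores.abs().to_numpy())
        )

    def test_no_moderation_is_ordinary_t(self, rng):
        mat, design = random_instance(rng)
        t = moderated_t(mat, design, prior_df=0.0)
        x1 = mat.values[list(design.class1)].to_numpy()
        x2 = mat.values[list(design.class2)].to_numpy()
        expected = [oracles.pooled_t_gene(x1[g], x2[g]) for g in range(40 if False else mat.n_probes)]
        assert t.scores.to_numpy() == pytest.approx(expected, abs=1e-10)

    def test_infinite_prior_uses_constant_denominator(self, rng):
        mat, design = random_instance(rng)
        t = moderated_t(mat, design, prior_df=np.inf)
        ad = ad_statistic(mat, design)
        # constant denominator => statistic proportional to AD
        ratio = t.scores.to_numpy() / ad.scores.to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_estimated_prior_matches_oracle_formula(self, rng):
        mat, design = random_instance(rng)
        t = moderated_t(mat, design)
        d0, s02 = t.params["d0"], t.params["s02"]
        x1 = mat.values[list(design.class1)].to_numpy()
        x2 = mat.values[list(design.class2)].to_numpy()
        expected = [
            oracles.moderated_t_gene(x1[g], x2[g], d0, s02)
            for g in range(mat.n_probes)
        ]
        assert t.scores.to_numpy() == pytest.approx(expected, abs=1e-10)


class TestSamT:
    def test_s0_zero_is_ordinary_t(self, rng):
        mat, design = random_instance(rng)
        t = sam_t(mat, design, s0=0.0)
        x1 = mat.values[list(design.class1)].to_numpy()
        x2 = mat.values[list(design.class2)].to_numpy()
        expected = [oracles.pooled_t_gene(x1[g], x2[g]) for g in range(mat.n_probes)]
        assert t.scores.to_numpy() == pytest.approx(expected, abs=1e-10)

    def test_huge_s0_ranks_like_ad(self, rng):
        mat, design = random_instance(rng)
        t = sam_t(mat, design, s0=1e9)
        ad = ad_statistic(mat, design)
        r1 = rank_genes(t, ties="average").to_numpy()
        r2 = rank_genes(ad, ties="average").to_numpy()
        assert r1 == pytest.approx(r2)

    def test_stabilises_low_variance_nulls(self, rng):
        # non-DEG genes with near-zero variance should fall in rank under samT
        m = 200
        base = rng.uniform(4, 10, size=(m, 1))
        x = base + rng.normal(0, 0.5, size=(m, 10))
        quiet = slice(0, 10)  # tiny-variance non-DEGs with tiny mean offsets
        x[quiet] = base[quiet] + rng.normal(0, 0.005, size=(10, 10))
        x[quiet, 5:] += 0.01
        mat = make_log2_matrix(x)
        design = make_design(mat)
        sam_ranks = rank_genes(sam_t(mat, design), ties="average")
        t_ranks = rank_genes(sam_t(mat, design, s0=0.0), ties="average")
        assert sam_ranks.iloc[quiet].mean() > t_ranks.iloc[quiet].mean()


class TestShrinkageT:
    def test_equal_variances_lambda_one_ranks_like_ad(self):
        x = np.array([[4.0, 5.0, 6.5, 7.5], [6.0, 7.0, 6.2, 7.2], [2.0, 3.0, 2.1, 3.1]])
        mat = make_log2_matrix(x)  # identical per-gene variance pattern
        t = shrinkage_t(mat, make_design(mat))
        assert t.params["lambda"] == 1.0
        ad = ad_statistic(mat, make_design(mat))
        assert np.argsort(-t.scores.abs().to_numpy()).tolist() == np.argsort(
            -ad.scores.abs().to_numpy()
        ).tolist()

    def test_lambda_zero_is_ordinary_t(self, rng):
        mat, design = random_instance(rng)
        t = shrinkage_t(mat, design, shrink_lambda=0.0)
        x1 = mat.values[list(design.class1)].to_numpy()
        x2 = mat.values[list(design.class2)].to_numpy()
        expected = [oracles.pooled_t_gene(x1[g], x2[g]) for g in range(mat.n_probes)]
        assert t.scores.to_numpy() == pytest.approx(expected, abs=1e-10)

    def test_lambda_in_unit_interval(self, rng):
        for seed in range(10):
            mat, design = random_instance(np.random.default_rng(seed))
            t = shrinkage_t(mat, design)
            assert 0.0 <= t.params["lambda"] <= 1.0


class TestIbmT:
    def test_flat_trend_agrees_with_moderated_t(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(4, 12, size=(300, 1))
        x = base + rng.normal(0, 0.5, size=(300, 8))  # variance independent of intensity
        mat = make_log2_matrix(x)
        design = make_design(mat)
        r1 = rank_genes(ibm_t(mat, design), ties="average")
        r2 = rank_genes(moderated_t(mat, design), ties="average")
        rho = np.corrcoef(r1, r2)[0, 1]
        assert rho > 0.99

    def test_intensity_prior_beats_flat_prior_on_average(self):
        # design premise of the method: with intensity-dependent noise, a
        # flat prior lets noisy-stratum null genes out-rank DEGs measured
        # elsewhere; the intensity-dependent prior recalibrates them.
        auc_ibm, auc_mod = [], []
        from degrank.evalmetrics import auc_from_ranks

        for seed in range(8):
            r = np.random.default_rng(seed)
            m = 200
            mean = np.sort(r.uniform(3, 12, m))[:, None]
            sd = (0.1 + 0.15 * (12 - mean)).clip(min=0.05)  # low intensity noisy
            x = mean + r.normal(0, 1, size=(m, 8)) * sd
            # DEGs in the quiet high-intensity stratum
            deg = m - 1 - r.choice(m // 3, 25, replace=False)
            x[deg, 4:] += 0.6 * r.choice([-1.0, 1.0], 25)[:, None]
            labels = pd.Series(False, index=[f"p{i:03d}" for i in range(m)])
            labels.iloc[deg] = True
            mat = make_log2_matrix(x)
            design = make_design(mat)
            auc_ibm.append(
                auc_from_ranks(rank_genes(ibm_t(mat, design), ties="average"), labels)
            )
            auc_mod.append(
                auc_from_ranks(rank_genes(moderated_t(mat, design), ties="average"), labels)
            )
        assert np.mean(auc_ibm) >= np.mean(auc_mod)

    def test_intensity_changes_statistic_when_trend_nonflat(self):
        rng = np.random.default_rng(11)
        m = 100
        mean = np.linspace(3, 12, m)[:, None]
        sd = 0.1 + 0.1 * (12 - mean)
        x = mean + rng.normal(0, 1, size=(m, 8)) * sd
        # plant two genes with identical difference and identical samples
        x[10] = np.concatenate([np.array([3, 3.1, 2.9, 3]), np.array([4, 4.1, 3.9, 4])])
        x[90] = x[10] + 8.0  # same variance, same difference, higher intensity
        mat = make_log2_matrix(x)
        t = ibm_t(mat, make_design(mat))
        assert t.scores.iloc[10] != pytest.approx(t.scores.iloc[90])


class TestRankGenes:
    def test_descending_abs_hand_sort(self):
        table = ScoreTable(
            "ad", pd.Series([0.1, 3.0, 2.0], index=list("abc")), DESCENDING_ABS
        )
        assert rank_genes(table).to_numpy() == pytest.approx([3, 1, 2])

    def test_rp_tie_average(self):
        table = ScoreTable("rp", pd.Series([1.0, 2.0, 1.0], index=list("abc")), ASCENDING)
        assert rank_genes(table, ties="average").to_numpy() == pytest.approx([1.5, 3, 1.5])

    def test_total_tie_average(self):
        table = ScoreTable("ad", pd.Series([1.0] * 5, index=list("abcde")), DESCENDING_ABS)
        assert set(rank_genes(table, ties="average")) == {3.0}

    def test_stable_tiebreak_by_probe_id(self):
        table = ScoreTable("rp", pd.Series([1.0, 2.0, 1.0], index=["z", "m", "a"]), ASCENDING)
        ranks = rank_genes(table, ties="stable")
        assert ranks["a"] == 1 and ranks["z"] == 2 and ranks["m"] == 3

    def test_nonfinite_raises(self):
        with pytest.raises(DataError):
            ScoreTable("ad", pd.Series([np.nan, 1.0]), DESCENDING_ABS)


# ---------------------------------------------------------------------------
# cross-method invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", METHODS)
def test_sign_flip_symmetry(method, rng):
    mat, design = random_instance(rng)
    flipped = ClassDesign(design.class2, design.class1)
    t_fwd = compute_statistic(method, mat, design)
    t_rev = compute_statistic(method, mat, flipped)
    if method == "rp":
        assert t_rev.scores.to_numpy() == pytest.approx(t_fwd.scores.to_numpy())
        assert t_rev.aux["rp_up"].to_numpy() == pytest.approx(
            t_fwd.aux["rp_down"].to_numpy()
        )
    else:
        assert t_rev.scores.to_numpy() == pytest.approx(-t_fwd.scores.to_numpy())
    r1 = rank_genes(t_fwd, ties="average").to_numpy()
    r2 = rank_genes(t_rev, ties="average").to_numpy()
    assert r1 == pytest.approx(r2)


@pytest.mark.parametrize("method", METHODS)
def test_within_class_permutation_invariance(method, rng):
    mat, design = random_instance(rng)
    shuffled = ClassDesign(design.class1[::-1], design.class2[::-1])
    s1 = compute_statistic(method, mat, design).scores.to_numpy()
    s2 = compute_statistic(method, mat, shuffled).scores.to_numpy()
    assert s1 == pytest.approx(s2)


def test_ad_equals_fc_on_constant_replicates(rng):
    values = np.repeat(rng.uniform(2, 10, size=(30, 2)), [2, 2], axis=1)
    mat = make_log2_matrix(values)
    design = make_design(mat)
    ad = ad_statistic(mat, design).scores.to_numpy()
    fc = fc_statistic(mat, design).scores.to_numpy()
    assert ad == pytest.approx(fc)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_rank_genes_is_permutation_without_ties(seed):
    r = np.random.default_rng(seed)
    scores = r.normal(size=20)
    table = ScoreTable("ad", pd.Series(scores, index=[f"p{i}" for i in range(20)]), DESCENDING_ABS)
    ranks = rank_genes(table, ties="stable")
    assert sorted(ranks) == list(range(1, 21))


def test_design_requires_two_reps_for_variance_methods():
    mat = make_log2_matrix([[1, 2], [3, 4]], ["A", "B"])
    with pytest.raises(DataError):
        moderated_t(mat, make_design(mat))


def test_design_missing_class():
    mat = make_log2_matrix([[1, 2, 3, 4]])
    with pytest.raises(DataError):
        ClassDesign.from_samples(mat.samples, "A", "X")
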