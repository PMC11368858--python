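import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from guttide.containers import AsvTable
from guttide.diversity import (
    aitchison_distance,
    alpha_diversity,
    anosim,
    clr_transform,
    pcoa,
    permanova,
    pielou,
    shannon,
    wilcoxon_rank_sum,
)
from tests.conftest import random_table


class TestAlpha:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([25, 25, 25, 25], np.log(4)),
            ([100, 0, 0], 0.0),
            # direct summation: -(1/4 ln 1/4 + 1/4 ln 1/4 + 1/2 ln 1/2)
            ([1, 1, 2], 1.0397207708399179),
        ],
    )
    def test_shannon_values(self, counts, expected):
        assert shannon(np.array(counts)) == pytest.approx(expected, abs=1e-10)

    def test_shannon_rejects_empty(self):
        with pytest.raises(ValueError):
            shannon(np.zeros(3))

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10, 10, 10, 10, 10], 1.0),
            ([1, 1, 2], 1.0397207708399179 / np.log(3)),  # = 0.94639...
        ],
    )
    def test_pielou_values(self, counts, expected):
        assert pielou(np.array(counts)) == pytest.approx(expected, abs=1e-10)

    def test_pielou_single_taxon_is_missing(self):
        assert np.isnan(pielou(np.array([7, 0, 0])))

    def test_alpha_diversity_frame(self, toy_table):
        alpha = alpha_diversity(toy_table)
        assert list(alpha.columns) == ["shannon", "observed_asvs", "pielou"]
        assert alpha.loc["S1", "observed_asvs"] == 3
        assert (alpha["shannon"] >= 0).all()
        assert alpha["pielou"].dropna().between(0, 1).all()


class TestClrAndAitchison:
    def test_equal_parts_map_to_zero(self):
        df = pd.DataFrame([[10, 10, 10, 10]], index=["S"], columns=list("ABCD"))
        clr = clr_transform(AsvTable(df), pseudocount=0)
        assert np.allclose(clr.values, 0)

    def test_two_part_value(self):
        # ln(x / sqrt(x1 x2)): ln(1/sqrt(10)) = -1.151292...
        df = pd.DataFrame([[1, 10]], index=["S"], columns=["A", "B"])
        clr = clr_transform(df, pseudocount=0)
        assert clr.values[0, 0] == pytest.approx(-np.log(10) / 2, abs=1e-12)
        assert clr.values[0, 1] == pytest.approx(np.log(10) / 2, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_clr_rows_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, 4, 6)
        clr = clr_transform(table, pseudocount=1.0)
        assert np.allclose(clr.sum(axis=1), 0, atol=1e-9)

    def test_identical_samples_distance_zero(self):
        df = pd.DataFrame([[3, 4, 5], [3, 4, 5]], index=["S1", "S2"], columns=list("ABC"))
        d = aitchison_distance(AsvTable(df))
        assert d["S1", "S2"] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_taxon_order(self, rng):
        table = random_table(rng, 5, 8)
        d1 = aitchison_distance(table)
        perm = rng.permutation(table.n_asvs)
        shuffled = AsvTable(table.counts.iloc[:, perm])
        d2 = aitchison_distance(shuffled)
        assert np.allclose(d1.data, d2.data)

    def test_scale_invariance_in_large_count_limit(self):
        # doubling a sample's counts leaves its clr (hence distances) unchanged
        # when the pseudocount is negligible relative to the counts
        base = np.array([[1000, 2000, 3000], [1500, 500, 4000]])
        df1 = pd.DataFrame(base, index=["S1", "S2"], columns=list("ABC"))
        df2 = pd.DataFrame(base * [[2], [1]], index=["S1", "S2"], columns=list("ABC"))
        d1 = aitchison_distance(AsvTable(df1))
        d2 = aitchison_distance(AsvTable(df2))
        assert d1["S1", "S2"] == pytest.approx(d2["S1", "S2"], abs=1e-3)


class TestPcoa:
    def test_two_samples(self):
        d = pd.DataFrame([[0, 3.0], [3.0, 0]], index=["a", "b"], columns=["a", "b"])
        res = pcoa(d)
        coords = res.coordinates["PC1"].to_numpy()
        assert sorted(np.abs(coords)) == pytest.approx([1.5, 1.5])

    def test_recovers_euclidean_configuration(self, rng):
        points = rng.normal(size=(5, 3))
        d = squareform(pdist(points))
        res = pcoa(pd.DataFrame(d, index=list("abcde"), columns=list("abcde")))
        recovered = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(recovered, d, atol=1e-8)

    def test_degenerate_all_zero(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        res = pcoa(d)
        assert np.allclose(res.eigenvalues, 0)

    def test_rejects_asymmetric(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            pcoa(d)

    def test_matches_skbio_and_clr_pca(self, rng):
        """PCoA on Aitchison distance == PCA of the clr matrix (cross-check)."""
        from sklearn.decomposition import PCA
        from skbio.stats.ordination import pcoa as skbio_pcoa

        table = random_table(rng, 8, 12)
        dist = aitchison_distance(table)
        ours = pcoa(dist, n_axes=3).coordinates.to_numpy()
        clr = clr_transform(table).to_numpy()
        ref_pca = PCA(n_components=3).fit_transform(clr)
        ref_skbio = skbio_pcoa(dist, method="eigh").samples.to_numpy()[:, :3]
        for ref in (ref_pca, ref_skbio):
            for axis in range(3):
                c = np.corrcoef(ours[:, axis], ref[:, axis])[0, 1]
                assert abs(c) > 1 - 1e-6


def _two_clouds(rng, n_per=6, sep=50.0):
    a = rng.normal(0, 1, size=(n_per, 3))
    b = rng.normal(sep, 1, size=(n_per, 3))
    pts = np.vstack([a, b])
    ids = [f"s{i}" for i in range(2 * n_per)]
    d = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
    groups = pd.Series(["a"] * n_per + ["b"] * n_per, index=ids)
    return d, groups


class TestGroupTests:
    def test_permanova_separated_clouds(self, rng):
        # with 12 per group no random permutation recreates the observed
        # grouping, so no permuted F can reach the observed one
        d, groups = _two_clouds(rng, n_per=12)
        res = permanova(d, groups, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.statistic > 100

    def test_permanova_relabel_invariance(self, rng):
        d, groups = _two_clouds(rng)
        order = rng.permutation(len(d))
        d2 = d.iloc[order, order]
        r1 = permanova(d, groups, n_perm=99, seed=1)
        r2 = permanova(d2, groups.iloc[order], n_perm=99, seed=1)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_permanova_reproducible_under_seed(self, rng):
        d, groups = _two_clouds(rng, sep=1.0)
        r1 = permanova(d, groups, n_perm=199, seed=5)
        r2 = permanova(d, groups, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value

    def test_small_group_rejected(self, rng):
        d, groups = _two_clouds(rng, n_per=2)
        groups.iloc[0] = "c"
        with pytest.raises(ValueError):
            permanova(d, groups, n_perm=99, seed=0)

    def test_anosim_maximal_separation(self, rng):
        d, groups = _two_clouds(rng, sep=100.0)
        res = anosim(d, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_anosim_monotone_invariance(self, rng):
        d, groups = _two_clouds(rng, sep=2.0)
        r1 = anosim(d, groups, n_perm=99, seed=3)
        r2 = anosim(np.sqrt(d), groups, n_perm=99, seed=3)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_anosim_null_mean_near_zero(self, rng):
        stats = []
        for _ in range(200):
            pts = rng.normal(size=(10, 2))
            ids = [f"s{i}" for i in range(10)]
            d = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
            groups = pd.Series(rng.permutation(["a"] * 5 + ["b"] * 5), index=ids)
            stats.append(anosim(d, groups, n_perm=99, seed=0).statistic)
        assert abs(np.mean(stats)) <= 0.05


class TestWilcoxon:
    def test_exact_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_shift_exact_p(self):
        # all 5 y above all 5 x: 2 of C(10,5)=252 orderings as extreme
        res = wilcoxon_rank_sum([1, 2, 3, 4, 5], [1001, 1002, 1003, 1004, 1005])
        assert res.p_value == pytest.approx(2 / 252)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
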