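import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guttide.diversity import clr_transform
from guttide.simulate import (
    SimulationConfig,
    brownian_traits,
    plant_correlations,
    simulate_communities,
    simulate_lognormal_counts,
    simulate_tree,
    taxonomy_from_tree,
)


def _newick(tree):
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


class TestSimulateTree:
    def test_tip_count(self):
        tree = simulate_tree(50, seed=1)
        assert sum(1 for _ in tree.tips()) == 50

    def test_deterministic_newick(self):
        assert _newick(simulate_tree(20, seed=9)) == _newick(simulate_tree(20, seed=9))
        assert _newick(simulate_tree(20, seed=9)) != _newick(simulate_tree(20, seed=10))

    def test_two_tips_is_cherry(self):
        tree = simulate_tree(2, seed=0)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert all(t.parent is tree for t in tips)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)

    def test_ultrametric_unit_height(self):
        tree = simulate_tree(30, seed=4)
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert np.allclose(list(depths.values()), 1.0)


class TestTraitsAndTaxonomy:
    def test_traits_deterministic_and_standardized(self):
        tree = simulate_tree(40, seed=2)
        t1 = brownian_traits(tree, seed=3, conservatism=2.0)
        t2 = brownian_traits(tree, seed=3, conservatism=2.0)
        pd.testing.assert_series_equal(t1, t2)
        assert t1.mean() == pytest.approx(0.0, abs=1e-12)
        assert t1.std() == pytest.approx(1.0)

    def test_conservatism_increases_phylogenetic_signal(self):
        # closely related tips should have more similar traits under a
        # front-loaded (early-burst) Brownian clock
        tree = simulate_tree(100, seed=5)
        from guttide.io import patristic_matrix

        d = patristic_matrix(tree).to_numpy()
        iu = np.triu_indices(100, 1)
        corrs = {}
        for a in (0.0, 3.0):
            tr = brownian_traits(tree, seed=6, conservatism=a)
            dt = np.abs(tr.to_numpy()[:, None] - tr.to_numpy()[None, :])
            corrs[a] = stats.spearmanr(d[iu], dt[iu])[0]
        assert corrs[3.0] > corrs[0.0] > 0

    def test_taxonomy_nested_and_complete(self):
        tree = simulate_tree(60, seed=7)
        tax = taxonomy_from_tree(tree)
        assert len(tax) == 60
        assert set(tax.columns) == {"phylum", "class", "order", "family", "genus"}
        assert tax.notna().all().all()
        # classes nest within phyla
        nesting = tax.groupby("class")["phylum"].nunique()
        assert (nesting == 1).all()


class TestSimulateCommunities:
    def test_default_design_arithmetic(self):
        cfg = SimulationConfig(n_asvs=60, seed=1)
        ds = simulate_communities(cfg)
        assert ds.table.n_samples == 108  # 9 animals x 4 timepoints x 3 sites
        assert len(ds.metadata) == 108
        assert set(ds.metadata["site"]) == {"Oc", "R", "F"}
        assert set(ds.metadata["timepoint"]) == {"1W", "2W", "1M", "2M"}
        assert ds.covariates.shape == (108, 16)

    def test_counts_respect_drawn_depth(self):
        cfg = SimulationConfig(n_asvs=50, n_animals=3, seed=2)
        ds = simulate_communities(cfg)
        # multinomial closure: row sums equal the drawn library sizes, which
        # are log-normal around 70k
        depths = ds.table.depths()
        assert (depths > 0).all()
        assert 50_000 < depths.mean() < 95_000

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_asvs=40, n_animals=3, seed=5)
        d1 = simulate_communities(cfg)
        d2 = simulate_communities(cfg)
        pd.testing.assert_frame_equal(d1.table.counts, d2.table.counts)
        pd.testing.assert_frame_equal(d1.covariates, d2.covariates)

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="unknown regime"):
            SimulationConfig(regimes={"Oc": "magic", "R": "drift", "F": "drift"})

    def test_truth_record_complete(self):
        cfg = SimulationConfig(n_asvs=40, n_animals=3, planted_pairs=2, seed=3)
        ds = simulate_communities(cfg)
        assert len(ds.truth.planted_rho) == 2
        assert set(ds.truth.regimes) == {"Oc", "R", "F"}
        assert ds.truth.basis.shape == ds.table.counts.shape
        assert len(ds.truth.traits) == 40

    def test_tvfa_is_component_sum(self):
        cfg = SimulationConfig(n_asvs=30, n_animals=3, seed=4)
        ds = simulate_communities(cfg)
        total = ds.covariates[["ACE", "PRO", "IBUT", "BUT", "IVAL", "VAL"]].sum(axis=1)
        assert np.allclose(ds.covariates["TVFA"], total)

    def test_selection_with_infinite_niche_width_degenerates_to_drift(self):
        """As the niche filter flattens, selection and drift produce
        indistinguishable turnover (KS on βNTI at alpha=0.01)."""
        from guttide.assembly import beta_nti

        pools = {"drift": [], "selection": []}
        for seed in (11, 12, 13):
            for regime in pools:
                cfg = SimulationConfig(
                    sites=("R",), regimes={"R": regime}, site_optima={"R": 2.0},
                    n_animals=4, timepoints=("1W", "2W"), n_asvs=80,
                    planted_pairs=0, selection_sigma=1e6, seed=seed,
                )
                ds = simulate_communities(cfg)
                z = beta_nti(ds.table, ds.tree, n_null=99, seed=1)
                pools[regime].extend(
                    z.values[np.triu_indices(ds.table.n_samples, 1)]
                )
        _, p = stats.ks_2samp(pools["drift"], pools["selection"])
        assert p > 0.01


class TestPlantCorrelations:
    def _base(self, n_samples=200, seed=0):
        cfg = SimulationConfig(
            sites=("R",), regimes={"R": "drift"}, site_optima={"R": 0.0},
            n_animals=n_samples // 4, timepoints=("1W", "2W", "1M", "2M"),
            n_asvs=50, planted_pairs=0, depth_log_mean=np.log(1e5),
            richness_fraction=0.8, seed=seed,
        )
        return simulate_communities(cfg)

    def test_strong_pair_visible_in_clr(self):
        ds = self._base()
        planted = plant_correlations(
            ds, [("ASV_0001", "ASV_0002")], strength=0.99, seed=1, sigma=1.0
        )
        clr = clr_transform(planted.table)
        r = np.corrcoef(clr["ASV_0001"], clr["ASV_0002"])[0, 1]
        assert r > 0.8

    def test_zero_strength_within_shuffle_null(self, rng):
        ds = self._base(n_samples=100, seed=2)
        planted = plant_correlations(
            ds, [("ASV_0001", "ASV_0002")], strength=0.0, seed=3, sigma=1.0
        )
        clr = clr_transform(planted.table)
        x, y = clr["ASV_0001"].to_numpy(), clr["ASV_0002"].to_numpy()
        r_obs = np.corrcoef(x, y)[0, 1]
        null = np.array(
            [np.corrcoef(x, rng.permutation(y))[0, 1] for _ in range(1000)]
        )
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= r_obs <= hi

    def test_deterministic_under_seed(self):
        ds = self._base(n_samples=40, seed=4)
        p1 = plant_correlations(ds, [("ASV_0001", "ASV_0002")], 0.8, seed=5)
        p2 = plant_correlations(ds, [("ASV_0001", "ASV_0002")], 0.8, seed=5)
        pd.testing.assert_frame_equal(p1.table.counts, p2.table.counts)

    def test_overlapping_pairs_rejected(self):
        ds = self._base(n_samples=40, seed=6)
        with pytest.raises(ValueError, match="overlap"):
            plant_correlations(
                ds, [("ASV_0001", "ASV_0002"), ("ASV_0002", "ASV_0003")], 0.5, seed=7
            )

    def test_truth_record_extended(self):
        ds = self._base(n_samples=40, seed=8)
        planted = plant_correlations(ds, [("ASV_0001", "ASV_0002")], 0.7, seed=9)
        assert planted.truth.planted_rho[("ASV_0001", "ASV_0002")] == 0.7


def test_lognormal_counts_helper_shapes_and_determinism():
    c1, b1 = simulate_lognormal_counts(30, 10, depth=5000, pairs=[(0, 1, 0.8)], seed=5)
    c2, _ = simulate_lognormal_counts(30, 10, depth=5000, pairs=[(0, 1, 0.8)], seed=5)
    pd.testing.assert_frame_equal(c1, c2)
    assert (c1.sum(axis=1) == 5000).all()
    assert b1.sum(axis=1).round(9).eq(1.0).all()
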