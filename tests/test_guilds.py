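"""Mixed-type distance, clustering, variance partitioning, guild profiles."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from genotrait.guilds import (
    DistanceMatrix,
    define_guilds,
    dendrogram_to_newick,
    guild_profiles,
    hierarchical_cluster,
    partition_r2,
    trait_correlations,
    variance_curve,
    wishart_distance,
)
from genotrait.synthetic import make_planted_guild_matrix
from genotrait.traits import TraitMatrix


def _tm(data, value_types):
    var = pd.DataFrame(
        {"value_type": value_types, "strategy": ["resource use"] * len(value_types)},
        index=data.columns,
    )
    return TraitMatrix(data=data, var=var)


def toy_matrix():
    """Two binary traits + one numeric trait over three genomes.

    Numeric values 1, 3, 5 → sample variance 4; hand-computed distances:
    d12² = (1/3)[(1−3)²/4 + 1 + 0] = 2/3
    d13² = (1/3)[(1−5)²/4 + 0 + 1] = 5/3
    d23² = (1/3)[(3−5)²/4 + 1 + 1] = 1
    """
    data = pd.DataFrame(
        {"b1": [0, 1, 0], "b2": [1, 1, 0], "x": [1.0, 3.0, 5.0]},
        index=["g1", "g2", "g3"],
    )
    return _tm(data, ["binary", "binary", "count"])


class TestWishartDistance:
    def test_matches_hand_computation(self):
        d = wishart_distance(toy_matrix())
        assert d.values[0, 1] == pytest.approx(np.sqrt(2 / 3))
        assert d.values[0, 2] == pytest.approx(np.sqrt(5 / 3))
        assert d.values[1, 2] == pytest.approx(1.0)

    def test_identical_rows_have_zero_distance(self):
        data = pd.DataFrame(
            {"b": [1, 1, 0], "x": [2.0, 2.0, 7.0]}, index=["g1", "g2", "g3"]
        )
        d = wishart_distance(_tm(data, ["binary", "count"]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_affine_scaling_of_numeric_columns_cancels(self):
        tm, _ = make_planted_guild_matrix(n_genomes=20, seed=81)
        base = wishart_distance(tm)
        scaled = tm.data.copy()
        for c in tm.columns_of_type("count"):
            scaled[c] = scaled[c] * 1e6 + 3.0
        d2 = wishart_distance(TraitMatrix(data=scaled, var=tm.var.copy()))
        assert np.allclose(base.values, d2.values)

    def test_genome_permutation_permutes_distances(self):
        tm, _ = make_planted_guild_matrix(n_genomes=15, seed=82)
        base = wishart_distance(tm)
        perm = np.random.default_rng(0).permutation(15)
        tm_p = TraitMatrix(data=tm.data.iloc[perm], var=tm.var.copy())
        d_p = wishart_distance(tm_p)
        assert np.allclose(d_p.values, base.values[np.ix_(perm, perm)])

    def test_constant_numeric_column_dropped_with_warning(self):
        data = pd.DataFrame(
            {"x": [1.0, 1.0, 1.0], "b": [0, 1, 0]}, index=["g1", "g2", "g3"]
        )
        with pytest.warns(UserWarning, match="constant"):
            d = wishart_distance(_tm(data, ["count", "binary"]))
        # only the binary column remains, p = 1
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_all_constant_columns_zero_matrix(self):
        data = pd.DataFrame({"x": [2.0, 2.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning):
            d = wishart_distance(_tm(data, ["count"]))
        assert (d.values == 0).all()

    def test_single_genome_rejected(self):
        data = pd.DataFrame({"b": [1]}, index=["g1"])
        with pytest.raises(ValueError, match="2 genomes"):
            wishart_distance(_tm(data, ["binary"]))


class TestHierarchicalClustering:
    def test_two_genomes_single_merge_at_their_distance(self):
        d = wishart_distance(
            _tm(pd.DataFrame({"b": [0, 1], "c": [1, 0]}, index=["g1", "g2"]),
                ["binary", "binary"])
        )
        linkage = hierarchical_cluster(d)
        assert linkage.shape == (1, 4)
        assert linkage[0, 2] == pytest.approx(d.values[0, 1])

    def test_merge_heights_non_decreasing(self):
        tm, _ = make_planted_guild_matrix(n_genomes=25, seed=83)
        linkage = hierarchical_cluster(wishart_distance(tm))
        assert (np.diff(linkage[:, 2]) >= -1e-12).all()

    def test_first_cut_separates_planted_blobs(self):
        tm, labels = make_planted_guild_matrix(
            n_genomes=30, n_guilds=2, divergence=0.9, noise=0.02, seed=84
        )
        d = wishart_distance(tm)
        linkage = hierarchical_cluster(d)
        cut = sch.cut_tree(linkage, n_clusters=2).ravel()
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, cut) == pytest.approx(1.0)

    def test_newick_has_all_leaves(self):
        tm, _ = make_planted_guild_matrix(n_genomes=10, seed=85)
        d = wishart_distance(tm)
        newick = dendrogram_to_newick(hierarchical_cluster(d), d.ids)
        assert newick.endswith(";")
        for genome_id in d.ids:
            assert genome_id in newick


def oracle_r2(d2, labels):
    """Direct implementation of the partition sum-of-squares formula."""
    n = len(labels)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
        ) / len(idx)
    return 1.0 - ss_within / ss_total


@pytest.fixture(scope="module")
def fixture20():
    tm, _ = make_planted_guild_matrix(n_genomes=20, seed=86)
    d = wishart_distance(tm)
    return d, hierarchical_cluster(d)


@pytest.fixture(scope="module")
def planted():
    tm, labels = make_planted_guild_matrix(seed=87)  # 60 genomes, 3 guilds
    d = wishart_distance(tm)
    linkage = hierarchical_cluster(d)
    return tm, labels, d, linkage


class TestVarianceCurve:
    def test_boundary_values(self, fixture20):
        d, linkage = fixture20
        curve = variance_curve(d, linkage)
        assert curve["r2"].iloc[0] == pytest.approx(0.0)  # k = 1
        assert curve["r2"].iloc[-1] == pytest.approx(1.0)  # k = n singletons
        assert curve["r2"].between(-1e-12, 1 + 1e-12).all()

    def test_non_decreasing_over_nested_cuts(self, fixture20):
        d, linkage = fixture20
        curve = variance_curve(d, linkage)
        assert (np.diff(curve["r2"]) >= -1e-9).all()

    def test_equals_direct_formula_oracle_for_all_k(self, fixture20):
        d, linkage = fixture20
        curve = variance_curve(d, linkage)
        d2 = d.values**2
        for _, row in curve.iterrows():
            labels = sch.cut_tree(linkage, n_clusters=int(row["k"])).ravel()
            assert row["r2"] == pytest.approx(oracle_r2(d2, list(labels)), abs=1e-10)

    def test_zero_total_variance_rejected(self):
        d = DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="undefined"):
            partition_r2(d, [1, 2])


class TestDefineGuilds:
    def test_variance_target_one_gives_singletons(self, planted):
        _, _, d, linkage = planted
        assignment = define_guilds(d, linkage, variance_target=1.0)
        assert assignment.k == d.n

    def test_planted_guilds_recovered_at_variance_target(self, planted):
        from sklearn.metrics import adjusted_rand_score

        _, labels, d, linkage = planted
        assignment = define_guilds(d, linkage, variance_target=0.7)
        assert assignment.k == 3
        assert adjusted_rand_score(labels, assignment.labels.values) == pytest.approx(1.0)

    def test_min_size_flags_small_guilds(self, planted):
        _, _, d, linkage = planted
        assignment = define_guilds(d, linkage, k=3, min_size=50)
        # 60 genomes in 3 guilds of ~20: all flagged, none removed
        assert assignment.flagged_small == [1, 2, 3]
        assert assignment.sizes.sum() == d.n

    def test_target_k_exclusivity_and_full_variance(self):
        data = pd.DataFrame({"b": [0, 1], "c": [0, 1]}, index=["g1", "g2"])
        d = wishart_distance(_tm(data, ["binary", "binary"]))
        linkage = hierarchical_cluster(d)
        assignment = define_guilds(d, linkage, variance_target=1.0)
        assert assignment.k == 2
        with pytest.raises(ValueError, match="exactly one"):
            define_guilds(d, linkage, k=2, variance_target=0.5)

    def test_labels_are_one_to_k(self, planted):
        _, _, d, linkage = planted
        assignment = define_guilds(d, linkage, k=4)
        assert sorted(assignment.labels.unique()) == [1, 2, 3, 4]


class TestGuildProfiles:
    def test_positivity_fraction(self):
        data = pd.DataFrame(
            {"b": [1, 1, 1, 0, 0, 0, 0, 0]}, index=[f"g{i}" for i in range(8)]
        )
        tm = _tm(data, ["binary"])
        from genotrait.guilds import GuildAssignment

        labels = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=data.index, name="guild")
        profile = guild_profiles(GuildAssignment(labels=labels, k=2), tm)
        assert profile.means.loc[1, "b"] == pytest.approx(0.75)
        assert profile.means.loc[2, "b"] == pytest.approx(0.0)

    def test_identical_guilds_not_significant(self):
        rng = np.random.default_rng(88)
        data = pd.DataFrame(
            {"c": rng.normal(size=20)}, index=[f"g{i}" for i in range(20)]
        )
        tm = _tm(data, ["count"])
        from genotrait.guilds import GuildAssignment

        # random split: no real across-guild signal
        labels = pd.Series([1, 2] * 10, index=data.index, name="guild")
        profile = guild_profiles(GuildAssignment(labels=labels, k=2), tm)
        assert profile.qvalues["c"] > 0.05

    def test_separating_trait_has_minimal_q(self):
        tm, labels = make_planted_guild_matrix(
            n_genomes=30, n_binary=5, n_count=0, n_guilds=2, divergence=0.9,
            noise=0.0, seed=89,
        )
        sep = pd.Series(
            (labels == 1).astype(int), index=tm.data.index, name="separator"
        )
        data = tm.data.copy()
        data["separator"] = sep
        var = tm.var.copy()
        var.loc["separator"] = ["binary", "resource use", "Planted", "Binary block", "separator"]
        tm2 = TraitMatrix(data=data, var=var)
        from genotrait.guilds import GuildAssignment

        assignment = GuildAssignment(
            labels=pd.Series(labels, index=tm.data.index, name="guild"), k=2
        )
        profile = guild_profiles(assignment, tm2)
        assert profile.qvalues["separator"] == profile.qvalues.min()

    def test_life_history_quantiles(self):
        tm, labels = make_planted_guild_matrix(n_genomes=12, n_guilds=2, seed=90)
        lh = pd.DataFrame(
            {"doubling_time_h": np.linspace(1, 12, 12)}, index=tm.data.index
        )
        from genotrait.guilds import GuildAssignment

        assignment = GuildAssignment(
            labels=pd.Series(labels, index=tm.data.index, name="guild"), k=2
        )
        profile = guild_profiles(assignment, tm, life_history=lh)
        assert profile.life_history is not None
        assert set(profile.life_history.index.get_level_values("quantile")) == {0.25, 0.5, 0.75}


class TestTraitCorrelations:
    def test_self_correlation_is_one(self):
        tm, _ = make_planted_guild_matrix(n_genomes=15, seed=91)
        corr = trait_correlations(tm)
        assert np.allclose(np.diag(corr), 1.0)

    def test_negation_is_minus_one(self):
        data = pd.DataFrame(
            {"b": [0, 1, 0, 1, 1], "nb": [1, 0, 1, 0, 0]},
            index=[f"g{i}" for i in range(5)],
        )
        corr = trait_correlations(_tm(data, ["binary", "binary"]))
        assert corr.loc["b", "nb"] == pytest.approx(-1.0)

    def test_equals_rank_then_pearson_oracle(self):
        from scipy.stats import rankdata

        tm, _ = make_planted_guild_matrix(n_genomes=20, n_binary=4, n_count=6, seed=92)
        corr = trait_correlations(tm)
        ranks = np.column_stack(
            [rankdata(tm.data[c]) for c in tm.data.columns]
        )
        oracle = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(corr.to_numpy(), oracle, atol=1e-12)

    def test_constant_trait_flagged_nan(self):
        data = pd.DataFrame(
            {"b": [0, 1, 0], "const": [1, 1, 1]}, index=["g1", "g2", "g3"]
        )
        corr = trait_correlations(_tm(data, ["binary", "binary"]))
        assert np.isnan(corr.loc["const"]).all()
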