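from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from endosig.enrich import (
    combine_by_protein,
    combine_isoform_pvalues,
    enrich_pipeline,
    expand_network,
    ks_enrichment,
    permutation_correct,
    transform_scores,
)


class TestFisherCombination:
    def test_k1_identity(self):
        assert combine_isoform_pvalues([0.05]).p == pytest.approx(0.05)

    def test_two_pvalues_closed_form(self):
        c = combine_isoform_pvalues([0.1, 0.1])
        assert c.statistic == pytest.approx(9.21034, abs=1e-5)
        assert c.df == 4
        # chi2(4) survival: exp(-X/2) * (1 + X/2)
        assert c.p == pytest.approx(np.exp(-c.statistic / 2) * (1 + c.statistic / 2),
                                    rel=1e-12)
        assert c.p == pytest.approx(0.056052, abs=1e-6)

    def test_all_ones(self):
        c = combine_isoform_pvalues([1.0, 1.0])
        assert c.statistic == 0.0 and c.p == pytest.approx(1.0)

    def test_zero_p_errors_unless_floored(self):
        with pytest.raises(ValueError):
            combine_isoform_pvalues([0.0, 0.5])
        assert combine_isoform_pvalues([0.0, 0.5], p_floor=1e-10).p < 1e-6

    def test_matches_numerical_integration(self, rng):
        """Chi-squared tail agrees with direct pdf integration for k <= 5."""
        for k in range(1, 6):
            p = rng.uniform(0.01, 0.99, size=k)
            c = combine_isoform_pvalues(p)
            tail, _ = integrate.quad(lambda t: stats.chi2.pdf(t, 2 * k),
                                     c.statistic, np.inf)
            assert c.p == pytest.approx(tail, abs=1e-10)

    def test_matches_scipy_combine(self, rng):
        p = rng.uniform(0.001, 1.0, size=4)
        ours = combine_isoform_pvalues(p)
        theirs = stats.combine_pvalues(p, method="fisher")
        assert ours.statistic == pytest.approx(theirs.statistic)
        assert ours.p == pytest.approx(theirs.pvalue)

    def test_combine_by_protein_groups(self):
        tab = pd.DataFrame({"protein": ["A", "A", "B"], "p": [0.1, 0.1, 0.5]})
        out = combine_by_protein(tab)
        assert out.loc["A", "k"] == 2 and out.loc["B", "k"] == 1
        assert out.loc["B", "p"] == pytest.approx(0.5)


class TestTransformScores:
    def test_values(self):
        s = transform_scores(pd.Series({"a": 0.01, "b": 1.0}))
        assert s["a"] == pytest.approx(2.0) and s["b"] == pytest.approx(0.0)

    def test_monotone_reversal(self, rng):
        p = pd.Series(rng.uniform(0.001, 1, 20))
        s = transform_scores(p)
        assert (np.argsort(p.to_numpy())[::-1] == np.argsort(s.to_numpy())).all()

    def test_domain(self):
        with pytest.raises(ValueError):
            transform_scores(pd.Series([0.0]))


class TestExpandNetwork:
    @pytest.fixture
    def net(self):
        g = nx.Graph()
        g.add_edge("m1", "u1", confidence=0.9)
        g.add_edge("m2", "u1", confidence=0.8)
        g.add_edge("m1", "u2", confidence=0.4)   # exactly at threshold: excluded
        g.add_edge("m1", "m2", confidence=0.95)
        g.add_node("lonely")
        return g

    def test_neighbor_mean(self, net):
        scores = pd.Series({"m1": 0.2, "m2": 0.4})
        out = expand_network(scores, net)
        assert out.loc["u1", "score"] == pytest.approx(0.3)
        assert out.loc["u1", "provenance"] == "expanded"

    def test_strict_confidence_threshold(self, net):
        out = expand_network(pd.Series({"m1": 0.2, "m2": 0.4}), net)
        assert "u2" not in out.index     # only reachable via a 0.4 edge
        assert "lonely" not in out.index

    def test_measured_nodes_keep_scores(self, net):
        scores = pd.Series({"m1": 0.2, "m2": 0.4})
        out = expand_network(scores, net)
        assert out.loc["m1", "score"] == 0.2 and out.loc["m2", "score"] == 0.4
        flipped = expand_network(scores, net, overwrite_measured=True)
        assert flipped.loc["m1", "score"] == pytest.approx(0.4)

    def test_subthreshold_edge_is_inert(self, net):
        scores = pd.Series({"m1": 0.2, "m2": 0.4})
        before = expand_network(scores, net)
        net.add_edge("m2", "u3", confidence=0.1)
        after = expand_network(scores, net)
        pd.testing.assert_frame_equal(before, after)

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="empty"):
            expand_network(pd.Series({"m1": 0.2}), nx.Graph())


class TestKsEnrichment:
    def test_disjoint_supports(self):
        scores = pd.Series({"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1})
        assert ks_enrichment(scores, {"a", "b"}) == pytest.approx(1.0)

    def test_identical_distributions(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 1.0, "d": 2.0})
        assert ks_enrichment(scores, {"a", "b"}) == pytest.approx(0.0)

    def test_full_universe_set_errors(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            ks_enrichment(scores, {"a", "b"})

    def test_matches_scipy_one_sided(self, rng):
        scores = pd.Series(rng.normal(size=30),
                           index=[f"g{i}" for i in range(30)])
        gene_set = {f"g{i}" for i in rng.choice(30, 8, replace=False)}
        ours = ks_enrichment(scores, gene_set)
        mask = scores.index.isin(gene_set)
        ref = stats.ks_2samp(scores[mask], scores[~mask],
                             alternative="less").statistic
        assert ours == pytest.approx(ref)

    def test_invariant_under_monotone_transform(self, rng):
        scores = pd.Series(rng.uniform(0.1, 5, 40),
                           index=[f"g{i}" for i in range(40)])
        gene_set = {f"g{i}" for i in range(10)}
        d1 = ks_enrichment(scores, gene_set)
        d2 = ks_enrichment(np.exp(2 * scores), gene_set)
        assert d1 == pytest.approx(d2)


class TestPermutationCorrect:
    def test_extreme_set_hits_lower_bound(self, rng):
        scores = pd.Series(rng.uniform(0, 1, 50),
                           index=[f"g{i}" for i in range(50)])
        top = set(scores.nlargest(10).index)
        res = permutation_correct(scores, {"top": top}, B=200, seed=0)
        assert res.loc["top", "p_perm"] == pytest.approx(1 / 201)

    def test_zero_statistic_gives_p_one(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 1.0, "d": 2.0})
        res = permutation_correct(scores, {"s": {"a", "b"}}, B=150, seed=0)
        assert res.loc["s", "D"] == 0.0
        assert res.loc["s", "p_perm"] == pytest.approx(1.0)

    def test_b_floor(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError):
            permutation_correct(scores, {"s": {"a"}}, B=50)

    def test_matches_full_enumeration_small_universe(self, rng):
        """Permutation p within Monte-Carlo error of exact subset enumeration."""
        genes = [f"g{i}" for i in range(8)]
        scores = pd.Series(rng.normal(size=8), index=genes)
        gene_set = set(genes[:3])
        vals = scores.to_numpy()
        from endosig.enrich import _ks_greater

        d_obs = ks_enrichment(scores, gene_set)
        null = [_ks_greater(vals[list(c)],
                            vals[[i for i in range(8) if i not in c]])
                for c in combinations(range(8), 3)]
        p_exact = np.mean([d >= d_obs for d in null])
        B = 4000
        res = permutation_correct(scores, {"s": gene_set}, B=B, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert abs(res.loc["s", "p_perm"] - p_exact) < 4 * se + 2 / B


def test_enrich_pipeline_planted_signal(rng):
    """A set holding the strongest proteins is detected; null sets are not."""
    proteins = [f"P{i}" for i in range(60)]
    iso = pd.DataFrame({
        "protein": np.repeat(proteins, 2),
        "p": np.concatenate([rng.uniform(1e-5, 0.01, 20),   # 10 hot proteins
                             rng.uniform(0.05, 1.0, 100)]),
    })
    g = nx.Graph()
    for i in range(59):
        g.add_edge(proteins[i], proteins[i + 1], confidence=0.9)
    g.add_edge("P0", "EXT1", confidence=0.95)
    sets = {"hot": set(proteins[:10]), "cold": set(proteins[40:55])}
    results, report = enrich_pipeline(iso, g, {"demo": sets}, B=2000, seed=3)
    res = results["demo"]
    assert res.loc["hot", "p_perm"] <= 0.01
    assert res.loc["cold", "p_perm"] > 0.05
    assert report["n_proteins_combined"] == 60
    assert report["n_expanded_universe"] == 61  # EXT1 picked up by expansion


def test_enrich_pipeline_empty_collection_warns(rng, caplog):
    iso = pd.DataFrame({"protein": ["A", "B"], "p": [0.5, 0.6]})
    g = nx.Graph()
    g.add_edge("A", "B", confidence=0.9)
    results, _ = enrich_pipeline(iso, g, {"empty": {}}, B=200, seed=0)
    assert results["empty"].empty
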