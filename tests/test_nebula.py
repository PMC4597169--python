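import numpy as np
import pytest

from conftest import network_from_edges
from hlanet.nebula import (
    NebulaConfig,
    POSITIVE,
    predict,
    predict_side_hla,
    predict_side_peptide,
    similarity_hla,
    similarity_peptide,
)
from hlanet.network import UndefinedMeanError
from oracles import naive_predict, random_bipartite_edges


def test_config_validation():
    with pytest.raises(ValueError):
        NebulaConfig(unbiased_leverage=2.5)
    with pytest.raises(ValueError):
        NebulaConfig(denominator_mode="signed")


class TestSimilarity:
    def test_no_shared_peptide_is_zero(self):
        net = network_from_edges({("A", "p1"): 2, ("B", "p2"): 1, ("A", "p3"): 1, ("B", "p3"): 1})
        # exclude the only shared edge pair context: A,B share only p3
        net2 = network_from_edges({("A", "p1"): 2, ("B", "p2"): 1})
        assert similarity_hla(net2, "A", "B") == 0.0

    def test_self_similarity_is_one_with_spread(self):
        net = network_from_edges({("A", "p1"): 2, ("A", "p2"): 1, ("A", "p3"): 2})
        assert similarity_hla(net, "A", "A") == 1.0

    def test_flat_profile_gives_zero(self):
        net = network_from_edges({("A", "p1"): 2, ("A", "p2"): 2, ("B", "p1"): 2, ("B", "p2"): 1})
        assert similarity_hla(net, "A", "B") == 0.0

    def test_three_point_profile_matches_textbook_pearson(self):
        # A: (2,2,1), B: (2,1,1) over shared peptides; node means over ALL edges
        edges = {("A", "p1"): 2, ("A", "p2"): 2, ("A", "p3"): 1,
                 ("B", "p1"): 2, ("B", "p2"): 1, ("B", "p3"): 1}
        net = network_from_edges(edges)
        ma, mb = 5 / 3, 4 / 3
        da = [2 - ma, 2 - ma, 1 - ma]
        db = [2 - mb, 1 - mb, 1 - mb]
        expected = sum(x * y for x, y in zip(da, db)) / (
            sum(x * x for x in da) * sum(y * y for y in db)
        ) ** 0.5
        assert similarity_hla(net, "A", "B") == pytest.approx(expected, abs=1e-12)

    def test_anticorrelated_two_point_profiles(self):
        edges = {("A", "p1"): 2, ("B", "p1"): 1, ("A", "p2"): 1, ("B", "p2"): 2}
        net = network_from_edges(edges)
        assert similarity_peptide(net, "p1", "p2") == pytest.approx(-1.0)

    def test_identical_profiles_with_spread(self):
        edges = {("A", "p1"): 2, ("B", "p1"): 1, ("A", "p2"): 2, ("B", "p2"): 1}
        net = network_from_edges(edges)
        assert similarity_peptide(net, "p1", "p2") == pytest.approx(1.0)

    def test_symmetry_and_bounds_on_random_networks(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            edges = random_bipartite_edges(rng)
            if not edges:
                continue
            net = network_from_edges(edges)
            hlas = net.hla_names
            for a in hlas:
                for b in hlas:
                    s_ab = similarity_hla(net, a, b)
                    s_ba = similarity_hla(net, b, a)
                    assert s_ab == pytest.approx(s_ba, abs=1e-12)
                    assert -1.0 <= s_ab <= 1.0

    def test_exclusion_changes_the_shared_set(self):
        edges = {("A", "p1"): 2, ("A", "p2"): 1, ("B", "p1"): 1, ("B", "p2"): 2}
        net = network_from_edges(edges)
        # excluding (A, p1) leaves only p2 shared -> single point -> 0
        assert similarity_hla(net, "A", "B", exclude=("A", "p1")) == 0.0


class TestSides:
    def test_all_positive_network_falls_back_to_node_mean(self):
        net = network_from_edges(
            {("A", "p1"): 2, ("A", "p2"): 2, ("B", "p1"): 2, ("B", "p2"): 2}
        )
        value, flag = predict_side_hla(net, "A", "p1")
        assert value == 2.0 and flag == "zero_denominator"

    def test_lonely_peptide_falls_back_to_hla_mean(self):
        net = network_from_edges({("A", "p1"): 2, ("A", "p2"): 1, ("B", "p2"): 2})
        value, flag = predict_side_hla(net, "A", "p1")
        assert value == pytest.approx(1.0)  # mean of A's other edge
        assert flag == "zero_denominator"

    def test_undefined_when_target_has_no_other_edge(self):
        net = network_from_edges({("A", "p1"): 2, ("B", "p1"): 1, ("B", "p2"): 2})
        value, flag = predict_side_hla(net, "A", "p1")
        assert value is None and flag == "undefined"

    @pytest.mark.parametrize("mode", ["literal", "absolute"])
    def test_three_by_three_matches_expanded_oracle(self, mode):
        edges = {("A", "p1"): 2, ("A", "p2"): 1, ("A", "p3"): 2,
                 ("B", "p1"): 2, ("B", "p2"): 2,
                 ("C", "p2"): 1, ("C", "p3"): 1}
        net = network_from_edges(edges)
        cfg = NebulaConfig(denominator_mode=mode)
        for (h, p) in edges:
            _, _, side_h, side_p = naive_predict(edges, h, p, mode=mode)
            got_h, _ = predict_side_hla(net, h, p, cfg)
            got_p, _ = predict_side_peptide(net, p, h, cfg)
            assert got_h == pytest.approx(side_h, abs=1e-10)
            assert got_p == pytest.approx(side_p, abs=1e-10)


class TestPredict:
    def test_boundary_score_is_positive_inclusive(self):
        # side means engineered to 2.0 (HLA) and 1.0 (peptide) with no
        # estimable similarities -> F = 1.5 exactly
        net = network_from_edges(
            {("A", "q1"): 2, ("A", "q2"): 2, ("B", "p"): 1, ("C", "p"): 1}
        )
        res = predict(net, "A", "p")
        assert res.F == 1.5
        assert res.C == POSITIVE

    def test_all_positive_training_network_predicts_two_everywhere(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            edges = {k: 2.0 for k in random_bipartite_edges(rng)}
            if len(edges) < 4:
                continue
            net = network_from_edges(edges)
            for h, p in edges:
                res = predict(net, h, p)
                if res.fallback_used != "global_mean":
                    assert res.F == pytest.approx(2.0)
                assert res.C == POSITIVE

    def test_global_mean_fallback_for_isolated_pair(self):
        net = network_from_edges({("A", "p1"): 2, ("B", "p1"): 2, ("A", "p2"): 1,
                                  ("C", "q"): 1, ("D", "q"): 1})
        # C's only edge is (C, q); q's only other edge is (D, q): exclude both
        res = predict(net, "C", "q")
        assert res.fallback_used != "global_mean"  # peptide side still defined via D
        # now a pair whose both sides vanish: single-edge endpoints
        net2 = network_from_edges({("A", "p1"): 2, ("B", "p2"): 1, ("B", "p1"): 1})
        res2 = predict(net2, "A", "p1")
        # A has no other edge; p1 has B -> peptide side defined
        assert res2.fallback_used == "hla_side_only" or res2.side_hla is None

    def test_global_fallback_disabled_raises(self):
        net = network_from_edges({("A", "p1"): 2, ("B", "p2"): 1, ("B", "p3"): 2})
        cfg = NebulaConfig(global_fallback=False)
        with pytest.raises(UndefinedMeanError):
            predict(net, "A", "p1", cfg)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(31)
        edges = random_bipartite_edges(rng)
        net = network_from_edges(edges)
        renamed = {(f"Z{h}", f"z{p}"): w for (h, p), w in edges.items()}
        net2 = network_from_edges(renamed)
        for h, p in edges:
            a = predict(net, h, p).F
            b = predict(net2, f"Z{h}", f"z{p}").F
            assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("mode", ["literal", "absolute"])
    def test_oracle_equivalence_on_random_networks(self, mode):
        rng = np.random.default_rng(41)
        cfg = NebulaConfig(denominator_mode=mode)
        checked = 0
        for _ in range(30):
            edges = random_bipartite_edges(rng)
            if len(edges) < 3:
                continue
            net = network_from_edges(edges)
            queries = list(edges) + [
                (h, p) for h in net.hla_names for p in net.peptide_names
                if (h, p) not in edges
            ]
            for h, p in queries:
                expected_F, expected_C, _, _ = naive_predict(edges, h, p, mode=mode)
                res = predict(net, h, p, cfg)
                assert res.F == pytest.approx(expected_F, abs=1e-10)
                assert res.C == expected_C
                checked += 1
        assert checked > 100

    def test_monotone_in_single_neighbour_regime(self):
        # with exactly one other supporter of p_x and a positive similarity,
        # flipping that supporter's edge to p_x from negative to positive
        # raises the HLA-side estimate by exactly 1 - 1/deg(supporter)
        rng = np.random.default_rng(53)
        cfg = NebulaConfig(denominator_mode="absolute")
        tested = 0
        for _ in range(200):
            edges = random_bipartite_edges(rng)
            net_edges = dict(edges)
            candidates = [
                (h, p) for (h, p), w in net_edges.items() if w == 1.0
            ]
            for j, px in candidates:
                supporters = [h for (h, p) in net_edges if p == px and h != j]
                if supporters:
                    continue  # want j to be the unique supporter of px for some target
                for target in {h for h, _ in net_edges} - {j}:
                    if (target, px) in net_edges:
                        continue
                    net_before = network_from_edges(net_edges)
                    flipped = dict(net_edges)
                    flipped[(j, px)] = 2.0
                    net_after = network_from_edges(flipped)
                    # precondition: the supporter's similarity is positive
                    # both before and after the flip
                    if (similarity_hla(net_before, target, j) <= 0
                            or similarity_hla(net_after, target, j) <= 0):
                        continue
                    before = predict_side_hla(net_before, target, px, cfg)
                    after = predict_side_hla(net_after, target, px, cfg)
                    if before[1] != "ok" or after[1] != "ok":
                        continue
                    assert after[0] >= before[0] - 1e-12
                    tested += 1
        assert tested > 5
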