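import numpy as np
import pandas as pd
import pytest

from conftest import network_from_edges
from hlanet.community import ModulePartition
from hlanet.profiles import (
    DEFAULT_SCHEME,
    AACategoryScheme,
    ContactResidueMap,
    extract_pseudo_sequence,
    highlight_nonmodal_residues,
    length_distribution,
    pairwise_identity,
    position_category_profile,
    pseudo_sequences,
    within_between_identity,
)
from hlanet.synthetic import generate_hla_alignment, benchmark_small


def test_default_scheme_partitions_the_twenty_residues():
    assert len(DEFAULT_SCHEME.members("polar_charged")) == 5
    assert len(DEFAULT_SCHEME.members("polar_uncharged")) == 7
    assert len(DEFAULT_SCHEME.members("apolar")) == 8
    assert DEFAULT_SCHEME.category("R") == "polar_charged"
    assert DEFAULT_SCHEME.category("G") == "polar_uncharged"
    assert DEFAULT_SCHEME.category("L") == "apolar"


def test_incomplete_scheme_rejected():
    with pytest.raises(ValueError):
        AACategoryScheme({"A": "apolar"})


class TestLengthDistribution:
    def _partition(self, pep_modules, hla_modules):
        mods = set(pep_modules.values()) | set(hla_modules.values())
        return ModulePartition(hla_modules, pep_modules, float("nan"), len(mods))

    def test_two_equal_modules_split_nine_mer_column(self):
        net = network_from_edges(
            {("A", "AAAAAAAAA"): 2, ("A", "CCCCCCCCC"): 2,
             ("B", "DDDDDDDDD"): 2, ("B", "EEEEEEEEE"): 2}
        )
        part = self._partition(
            {"AAAAAAAAA": 1, "CCCCCCCCC": 1, "DDDDDDDDD": 2, "EEEEEEEEE": 2},
            {"A": 1, "B": 2},
        )
        table = length_distribution(part, net)
        assert table.percent.loc[1, "9"] == pytest.approx(50.0)
        assert table.percent.loc[2, "9"] == pytest.approx(50.0)
        assert table.counts.loc[1, "HLA count"] == 1

    def test_single_module_columns_are_all_hundred(self):
        net = network_from_edges({("A", "AAAAAAA"): 2, ("A", "CCCCCCCCCCCC"): 1})
        part = self._partition({"AAAAAAA": 1, "CCCCCCCCCCCC": 1}, {"A": 1})
        table = length_distribution(part, net)
        assert table.percent.loc[1, "7"] == pytest.approx(100.0)
        assert table.percent.loc[1, ">11"] == pytest.approx(100.0)

    def test_columns_sum_to_hundred_and_total_matches(self, bench_network, bench_partition):
        table = length_distribution(bench_partition, bench_network)
        sums = table.percent.sum(axis=0).dropna()
        assert np.allclose(sums, 100.0)
        assert table.counts["Total"].sum() == bench_network.n_peptides
        assert table.counts["HLA count"].sum() == bench_network.n_hlas


class TestPositionCategoryProfile:
    def test_all_apolar(self):
        prof = position_category_profile(["AAAAAAAAA"], 9)
        assert (prof["apolar"] == 1.0).all()

    def test_even_mixture(self):
        prof = position_category_profile(["RRRRRRRRR", "SSSSSSSSS"], 9)
        assert (prof["polar_charged"] == 0.5).all()
        assert (prof["polar_uncharged"] == 0.5).all()

    def test_hand_counted_set(self):
        # position 1: 4 charged (R,D,E,K), 3 uncharged (S,T,N), 3 apolar (A,L,V)
        peptides = [aa + "AAAAAAAA" for aa in "RDEKSTNALV"]
        prof = position_category_profile(peptides, 9)
        assert prof.loc[1, "polar_charged"] == pytest.approx(0.4)
        assert prof.loc[1, "polar_uncharged"] == pytest.approx(0.3)
        assert prof.loc[1, "apolar"] == pytest.approx(0.3)
        assert (prof.loc[2:, "apolar"] == 1.0).all()

    def test_rows_sum_to_one(self, bench_data):
        records, labels = bench_data
        nine = [p for p in {r.peptide for r in records} if len(p) == 9]
        prof = position_category_profile(nine, 9)
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_wrong_length_is_fatal(self):
        with pytest.raises(ValueError):
            position_category_profile(["AAAA"], 9)


class TestPseudoSequences:
    def test_direct_indexing(self):
        cmap = ContactResidueMap({1: [2, 3]})
        assert extract_pseudo_sequence("KWV", cmap, 1) == "KW"

    def test_residues_taken_in_ascending_order(self):
        cmap = ContactResidueMap({1: [4, 2]})
        assert extract_pseudo_sequence("KWV", cmap, 1) == "KV"

    def test_empty_contact_list_rejected(self):
        with pytest.raises(ValueError):
            ContactResidueMap({1: []})

    def test_out_of_range_contact_rejected(self):
        with pytest.raises(ValueError, match="183"):
            ContactResidueMap({1: [183]})

    def test_contact_beyond_row_is_fatal(self):
        cmap = ContactResidueMap({1: [50]})
        with pytest.raises(ValueError, match="50"):
            extract_pseudo_sequence("KWV", cmap, 1)

    def test_identical_rows_identical_pseudo_sequences(self):
        cmap = ContactResidueMap.default()
        row = "M" * 181
        assert extract_pseudo_sequence(row, cmap, 2) == extract_pseudo_sequence(row, cmap, 2)

    def test_default_map_covers_nine_positions_in_range(self):
        cmap = ContactResidueMap.default()
        assert set(cmap.positions) == set(range(1, 10))
        for pos in range(1, 10):
            assert all(2 <= r <= 182 for r in cmap.residues(pos))


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDE", "ACDE") == 1.0

    def test_three_quarters(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_fully_distinct(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_symmetric_and_one_iff_equal(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFG")
        for _ in range(50):
            a = "".join(rng.choice(aas, size=6))
            b = "".join(rng.choice(aas, size=6))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)
            assert (pairwise_identity(a, b) == 1.0) == (a == b)

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            pairwise_identity("AA", "AAA")


class TestWithinBetweenIdentity:
    def test_internally_identical_mutually_distinct(self):
        seqs = {"a1": "AAAA", "a2": "AAAA", "b1": "CCCC", "b2": "CCCC"}
        mods = {"a1": 1, "a2": 1, "b1": 2, "b2": 2}
        out = within_between_identity(mods, seqs)
        assert out.loc[1, "within_mean"] == 1.0
        assert out.loc[1, "between_mean"] == 0.0

    def test_all_identical_is_degenerate(self):
        seqs = {k: "AAAA" for k in "abcd"}
        mods = {"a": 1, "b": 1, "c": 2, "d": 2}
        out = within_between_identity(mods, seqs)
        assert (out["within_mean"] == 1.0).all()
        assert (out["between_mean"] == 1.0).all()
        assert out["p_value"].isna().all()

    def test_singleton_module_reported_undefined(self):
        seqs = {"a": "AAAA", "b": "CCCC", "c": "CCCA"}
        out = within_between_identity({"a": 1, "b": 2, "c": 2}, seqs)
        assert np.isnan(out.loc[1, "within_mean"])
        assert np.isnan(out.loc[1, "p_value"])

    @pytest.mark.parametrize("test", ["mannwhitney", "permutation"])
    def test_generator_alignment_separates_modules(self, test):
        spec = benchmark_small(seed=2)
        alignment, cmap = generate_hla_alignment(spec)
        mods = {name: int(name[6:8]) - 70 for name in alignment}
        pseudo = pseudo_sequences(alignment, cmap, 2)
        out = within_between_identity(mods, pseudo, test=test, seed=0)
        assert (out["within_mean"] > out["between_mean"]).all()
        assert (out["p_value"] < 0.05).all()

    def test_label_permutation_p_is_roughly_uniform_under_null(self):
        # identities carry no module signal -> permutation p should not pile up near 0
        rng = np.random.default_rng(8)
        ps = []
        for rep in range(20):
            seqs = {f"s{i}": "".join(rng.choice(list("AC"), size=12)) for i in range(8)}
            mods = {f"s{i}": 1 if i < 4 else 2 for i in range(8)}
            out = within_between_identity(
                mods, seqs, test="permutation", n_permutations=99, seed=rep
            )
            ps.extend(out["p_value"].dropna().tolist())
        assert np.mean(ps) > 0.25
        assert min(ps) > 1 / 100.0 - 1e-9  # add-one estimator bounds p away from 0


class TestHighlightNonmodal:
    def test_uniform_column_unannotated(self):
        out = highlight_nonmodal_residues({"x": "A", "y": "A"})
        assert out.empty

    def test_minority_residue_annotated_with_category(self):
        out = highlight_nonmodal_residues({"x": "A", "y": "A", "z": "R"})
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["allele"], row["residue"], row["category"]) == ("z", "R", "polar_charged")
        assert row["residue_number"] == 2  # first column = mature-chain residue 2

    def test_tie_broken_alphabetically(self):
        out = highlight_nonmodal_residues({"x": "A", "y": "R"})
        # tie between A and R: A is modal, R annotated; deterministic
        assert list(out["residue"]) == ["R"]
        out2 = highlight_nonmodal_residues({"x": "R", "y": "A"})
        assert list(out2["residue"]) == ["R"]

    def test_ragged_alignment_fatal(self):
        with pytest.raises(ValueError):
            highlight_nonmodal_residues({"x": "AA", "y": "A"})
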