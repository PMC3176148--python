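import math

import numpy as np
import pytest

from teclass.errors import PartitionError
from teclass.jtt import EvolutionaryDistanceMatrix
from teclass.studies import toy_z_matrix, toy_z_oracle
from teclass.subfamilies import (
    SubfamilyPartition,
    ZTestRecord,
    membership_violations,
    pair_statistics,
    propose_initial_partition,
    refine_partition,
    validate_partition,
    z_value,
)
from teclass.trees import PhylogeneticTree


def block_matrix(n_a=4, n_b=4, intra=0.1, inter=0.9):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    n = n_a + n_b
    d = np.full((n, n), inter)
    d[:n_a, :n_a] = intra
    d[n_a:, n_a:] = intra
    np.fill_diagonal(d, 0.0)
    return EvolutionaryDistanceMatrix(ids, d, np.zeros((n, n), int), {})


GROUP_A = {f"a{i}" for i in range(4)}
GROUP_B = {f"b{i}" for i in range(4)}


class TestPairStatistics:
    def test_constant_blocks(self):
        D = block_matrix()
        rec = pair_statistics(D, GROUP_A, GROUP_B)
        assert rec.d_inter == pytest.approx(0.9)
        assert rec.d_intra_pooled == pytest.approx(0.1)
        assert rec.var_inter == rec.var_intra_pooled == 0.0
        assert (rec.n_ij, rec.n_ii, rec.n_jj) == (16, 6, 6)

    def test_toy_matrix_matches_direct_arithmetic(self):
        D = toy_z_matrix()
        rec = pair_statistics(D, GROUP_A, GROUP_B)
        # brute-force over the enumerated pairs
        import itertools

        ia = [D.index(x) for x in sorted(GROUP_A)]
        ib = [D.index(x) for x in sorted(GROUP_B)]
        cross = [D.d[i, j] for i in ia for j in ib]
        wa = [D.d[i, j] for i, j in itertools.combinations(ia, 2)]
        wb = [D.d[i, j] for i, j in itertools.combinations(ib, 2)]
        assert rec.d_inter == pytest.approx(np.mean(cross), abs=1e-15)
        assert rec.d_ii == pytest.approx(np.mean(wa), abs=1e-15)
        assert rec.d_jj == pytest.approx(np.mean(wb), abs=1e-15)
        pooled = (sum(wa) + sum(wb)) / (len(wa) + len(wb))
        assert rec.d_intra_pooled == pytest.approx(pooled, abs=1e-15)
        assert rec.var_inter == pytest.approx(np.var(cross), abs=1e-15)

    def test_symmetry_under_group_swap(self):
        D = toy_z_matrix()
        r1 = pair_statistics(D, GROUP_A, GROUP_B)
        r2 = pair_statistics(D, GROUP_B, GROUP_A)
        assert r1.d_inter == r2.d_inter
        assert r1.d_ii == r2.d_jj and r1.d_jj == r2.d_ii
        assert r1.d_intra_pooled == r2.d_intra_pooled
        assert r1.var_intra_pooled == r2.var_intra_pooled

    def test_contract_errors(self):
        D = block_matrix()
        with pytest.raises(PartitionError, match="overlap"):
            pair_statistics(D, GROUP_A, GROUP_A | {"b0"})
        with pytest.raises(PartitionError, match=">= 2"):
            pair_statistics(D, {"a0"}, GROUP_B)


class TestZValue:
    def test_toy_matrix_both_count_conventions(self):
        for counts in ("pairs", "taxa"):
            z_pkg, z_direct = toy_z_oracle(counts)
            assert z_pkg == pytest.approx(z_direct, abs=1e-12)

    def test_symmetric_in_groups(self):
        D = toy_z_matrix()
        z1 = z_value(pair_statistics(D, GROUP_A, GROUP_B))
        z2 = z_value(pair_statistics(D, GROUP_B, GROUP_A))
        assert z1 == z2

    def test_null_when_means_equal(self):
        rec = ZTestRecord("A", "B", 0.5, 0.5, 0.5, 0.5, 0.01, 0.01, 16, 6, 6)
        assert z_value(rec) == 0.0

    def test_degenerate_separation_is_flagged_infinite(self):
        rec = ZTestRecord("A", "B", 0.9, 0.1, 0.1, 0.1, 0.0, 0.0, 16, 6, 6)
        assert z_value(rec) == math.inf and rec.degenerate
        rec0 = ZTestRecord("A", "B", 0.1, 0.1, 0.1, 0.1, 0.0, 0.0, 16, 6, 6)
        assert z_value(rec0) == 0.0 and not rec0.degenerate

    def test_variance_doubling_scales_z_by_inverse_root_two(self):
        rec = ZTestRecord("A", "B", 0.9, 0.1, 0.1, 0.1, 0.02, 0.01, 16, 6, 6)
        z1 = z_value(rec)
        rec2 = ZTestRecord("A", "B", 0.9, 0.1, 0.1, 0.1, 0.04, 0.02, 16, 6, 6)
        assert z_value(rec2) == pytest.approx(z1 / math.sqrt(2), rel=1e-12)


class TestValidatePartition:
    def test_undersized_group_fails_membership(self):
        D = block_matrix()
        part = SubfamilyPartition(
            {"A": GROUP_A, "B": GROUP_B}, set()
        )
        report = validate_partition(D, part, min_size=5)
        assert not report.passed
        assert any("sequences" in v for v in report.violations)

    def test_species_rule(self):
        part = SubfamilyPartition({"A": GROUP_A}, set())
        species = {m: "same_species" for m in GROUP_A}
        out = membership_violations(part, species, 4, None)
        assert out and "species" in out[0]

    def test_degenerate_pass_with_flag(self):
        D = block_matrix()
        part = SubfamilyPartition({"A": GROUP_A, "B": GROUP_B}, set())
        report = validate_partition(D, part, min_size=4)
        assert report.passed
        assert report.records[0].degenerate

    def test_simulated_three_subfamilies_pass(self, three_clade_sim):
        report = validate_partition(
            three_clade_sim["D"],
            three_clade_sim["truth"],
            species_of=three_clade_sim["species"],
        )
        assert report.passed
        assert report.min_z() > 3.3
        assert len(report.records) == 3

    def test_json_report_serializes(self, tmp_path):
        D = block_matrix()
        part = SubfamilyPartition({"A": GROUP_A, "B": GROUP_B}, set())
        report = validate_partition(D, part, min_size=4)
        text = report.to_json(tmp_path / "r.json")
        assert '"passed": true' in text


def two_clade_tree(support=100.0):
    labels = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    t = PhylogeneticTree(labels)
    u, v = t.new_node(), t.new_node()
    for i in range(5):
        t.add_edge(u, i, 0.05)
        t.add_edge(v, 5 + i, 0.05)
    eid = t.add_edge(u, v, 1.0)
    if support is not None:
        t.supports[eid] = support
    return t


class TestProposeInitialPartition:
    def test_perfect_two_clade_tree(self):
        t = two_clade_tree()
        part = propose_initial_partition(t, min_size=5)
        assert len(part.groups) == 2 and not part.non_grouped
        assert {frozenset(g) for g in part.groups.values()} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_star_tree_all_non_grouped(self):
        labels = [f"t{i}" for i in range(6)]
        t = PhylogeneticTree(labels)
        hub = t.new_node()
        for i in range(6):
            t.add_edge(hub, i, 0.1)
        part = propose_initial_partition(t)
        assert not part.groups and part.non_grouped == set(labels)

    def test_low_support_edges_ignored(self):
        t = two_clade_tree(support=40.0)
        part = propose_initial_partition(t, min_size=5)
        assert not part.groups

    def test_nested_supported_clades_take_outermost(self):
        # 12 tips: clade of 6 containing a supported subclade of 5
        labels = [f"x{i}" for i in range(6)] + [f"y{i}" for i in range(6)]
        t = PhylogeneticTree(labels)
        inner = t.new_node()
        for i in range(1, 6):
            t.add_edge(inner, i, 0.05)
        outer = t.new_node()
        e_in = t.add_edge(outer, inner, 0.2)
        t.add_edge(outer, 0, 0.05)
        other = t.new_node()
        for i in range(6, 12):
            t.add_edge(other, i, 0.05)
        e_out = t.add_edge(outer, other, 1.0)
        t.supports[e_in] = 95.0
        t.supports[e_out] = 98.0
        part = propose_initial_partition(t, min_size=5)
        # oracle: enumerate all supported candidate clades explicitly
        assert frozenset(f"x{i}" for i in range(6)) in {
            frozenset(g) for g in part.groups.values()
        }
        assert not any(
            frozenset(g) == frozenset(f"x{i}" for i in range(1, 6))
            for g in part.groups.values()
        )


class TestRefinePartition:
    def test_already_valid_is_fixed_point(self, three_clade_sim):
        D, tree = three_clade_sim["D"], three_clade_sim["tree"]
        truth, species = three_clade_sim["truth"], three_clade_sim["species"]
        final, log = refine_partition(D, tree, truth, species_of=species)
        assert final.groups == truth.groups
        assert log == []

    def test_artificially_split_clade_is_merged(self, three_clade_sim):
        D, tree = three_clade_sim["D"], three_clade_sim["tree"]
        truth, species = three_clade_sim["truth"], three_clade_sim["species"]
        groups = {k: set(v) for k, v in truth.groups.items()}
        sf1 = sorted(groups.pop("SF1"))
        # split SF1 along a real subclade so both halves are tree clades
        clades = tree.clade_sets()
        sub = next(
            c for c in clades
            if c < frozenset(sf1) and 3 <= len(c) <= 7
        )
        groups["SF1a"] = set(sub)
        groups["SF1b"] = set(sf1) - set(sub)
        init = SubfamilyPartition(groups)
        final, log = refine_partition(
            D, tree, init, min_size=3, species_of=species, min_species=3
        )
        assert {frozenset(v) for v in final.groups.values()} == {
            frozenset(v) for v in truth.groups.values()
        }
        assert any("merge" in entry for entry in log)

    def test_rogue_sequence_is_ejected(self):
        # clean 5+5 blocks, then poison one member of A with huge distances
        D = block_matrix(n_a=5, n_b=5)
        d = D.d.copy()
        rogue = D.index("a4")
        d[rogue, :] = 3.0
        d[:, rogue] = 3.0
        d[rogue, rogue] = 0.0
        D2 = EvolutionaryDistanceMatrix(D.ids, d, D.shared_sites, {})
        init = SubfamilyPartition(
            {"A": {f"a{i}" for i in range(5)},
             "B": {f"b{i}" for i in range(5)}}
        )
        tree = two_clade_tree()  # union A|B is not a clade once poisoned
        final, log = refine_partition(
            D2, tree, init, min_size=4, min_species=1
        )
        assert "a4" in final.non_grouped
        assert any("eject a4" in entry for entry in log)

    def test_structureless_data_never_keeps_two_groups(self):
        # all distances equal: no split is ever significant, so the
        # refinement can never end with two certified subfamilies
        n = 8
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        ids = [f"s{i}" for i in range(n)]
        D = EvolutionaryDistanceMatrix(ids, d, np.zeros((n, n), int), {})
        init = SubfamilyPartition(
            {"A": set(ids[:4]), "B": set(ids[4:])}
        )
        tree = PhylogeneticTree(ids)  # star: the union is never a clade
        hub = tree.new_node()
        for i in range(n):
            tree.add_edge(hub, i, 0.25)
        final, log = refine_partition(
            D, tree, init, min_size=4, min_species=1
        )
        assert len(final.groups) <= 1  # no spurious pair of subfamilies
        assert final.non_grouped
        assert log  # every eject/dissolve action is audited
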