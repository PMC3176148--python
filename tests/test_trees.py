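import itertools

import numpy as np
import pytest

from teclass.errors import TreeError
from teclass.jtt import EvolutionaryDistanceMatrix
from teclass.synthetic import SequenceSimSpec, simulate_subfamily_alignment
from teclass.trees import (
    BootstrapConfig,
    PhylogeneticTree,
    bootstrap_supports,
    build_tree,
    majority_rule_consensus,
    minimum_evolution_refine,
    neighbor_joining,
    ols_branch_lengths,
    root_with_outgroup,
    unroot,
)

from conftest import additive_matrix


def quartet_matrix():
    """Additive 4-taxon matrix: pendants 0.1/0.2/0.3/0.4, internal 0.5."""
    ids = ["A", "B", "C", "D"]
    return additive_matrix(
        {
            frozenset({"A"}): 0.1,
            frozenset({"B"}): 0.2,
            frozenset({"C"}): 0.3,
            frozenset({"D"}): 0.4,
            frozenset({"A", "B"}): 0.5,
        },
        ids,
    )


def _canonical(side: frozenset, all_tips: frozenset) -> frozenset:
    comp = all_tips - side
    if len(side) != len(comp):
        return side if len(side) < len(comp) else comp
    return min(side, comp, key=sorted)


def tip_sets(tree):
    all_tips = frozenset(tree.tip_labels)
    return {
        _canonical(frozenset(tree.tip_labels[i] for i in s), all_tips)
        for s in tree.bipartitions()
    }


def split_lengths(tree):
    all_tips = frozenset(tree.tip_labels)
    out = {}
    for eid, _ in tree.live_edges():
        side = frozenset(tree.tip_labels[i] for i in tree.edge_side(eid))
        out[_canonical(side, all_tips)] = tree.lengths[eid]
    return out


class TestNeighborJoining:
    def test_recovers_additive_quartet_exactly(self):
        D = quartet_matrix()
        tree = neighbor_joining(D)
        # oracle: OLS-fit all three unrooted quartet topologies; the true
        # one is the unique perfect (zero-residual) fit
        best = None
        for split in [{"A", "B"}, {"A", "C"}, {"A", "D"}]:
            t = _quartet_tree(split)
            fitted = ols_branch_lengths(t, D)
            resid = _residual(fitted, D)
            if best is None or resid < best[0]:
                best = (resid, split)
        assert best[1] == {"A", "B"} and best[0] < 1e-18
        assert tip_sets(tree) == {frozenset({"C", "D"})} or tip_sets(
            tree
        ) == {frozenset({"A", "B"})}
        lengths = split_lengths(tree)
        assert lengths[frozenset({"A"})] == pytest.approx(0.1, abs=1e-9)
        assert lengths[frozenset({"D"})] == pytest.approx(0.4, abs=1e-9)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        D = EvolutionaryDistanceMatrix(
            ["a", "b", "c"], d, np.zeros((3, 3), int), {}
        )
        tree = neighbor_joining(D)
        lengths = split_lengths(tree)
        assert lengths[frozenset({"a"})] == pytest.approx(0.1)
        assert lengths[frozenset({"b"})] == pytest.approx(0.2)
        assert lengths[frozenset({"c"})] == pytest.approx(0.4)

    def test_row_permutation_invariance(self):
        D = quartet_matrix()
        perm = [2, 0, 3, 1]
        ids = [D.ids[i] for i in perm]
        Dp = EvolutionaryDistanceMatrix(
            ids, D.d[np.ix_(perm, perm)], D.shared_sites[np.ix_(perm, perm)],
            {},
        )
        assert tip_sets(neighbor_joining(D)) == tip_sets(neighbor_joining(Dp))
        assert split_lengths(neighbor_joining(D)) == pytest.approx(
            split_lengths(neighbor_joining(Dp))
        )

    def test_too_few_taxa(self):
        d = np.zeros((2, 2))
        D = EvolutionaryDistanceMatrix(["a", "b"], d, d.astype(int), {})
        with pytest.raises(TreeError, match=">= 3"):
            neighbor_joining(D)


def _quartet_tree(ab_split):
    ids = ["A", "B", "C", "D"]
    t = PhylogeneticTree(ids)
    left = sorted(ab_split)
    right = sorted(set(ids) - ab_split)
    u, v = t.new_node(), t.new_node()
    t.add_edge(u, ids.index(left[0]))
    t.add_edge(u, ids.index(left[1]))
    t.add_edge(v, ids.index(right[0]))
    t.add_edge(v, ids.index(right[1]))
    t.add_edge(u, v)
    return t


def _residual(tree, D):
    lengths = split_lengths(tree)
    resid = 0.0
    for i, a in enumerate(D.ids):
        for b in D.ids[i + 1:]:
            path = sum(
                l for s, l in lengths.items() if (a in s) != (b in s)
            )
            resid += (path - D.d[D.index(a), D.index(b)]) ** 2
    return resid


class TestMinimumEvolution:
    def test_additive_matrix_is_fixed_point(self):
        D = quartet_matrix()
        nj = neighbor_joining(D)
        refined = minimum_evolution_refine(nj, D)
        assert tip_sets(refined) == tip_sets(nj)
        assert split_lengths(refined) == pytest.approx(split_lengths(nj))

    def test_restores_true_topology_after_nni_perturbation(self):
        # five-taxon caterpillar; oracle = exhaustive 15-topology OLS scan
        ids = ["A", "B", "C", "D", "E"]
        true_splits = {
            frozenset({"A"}): 0.10, frozenset({"B"}): 0.15,
            frozenset({"C"}): 0.20, frozenset({"D"}): 0.25,
            frozenset({"E"}): 0.30,
            frozenset({"A", "B"}): 0.40, frozenset({"D", "E"}): 0.35,
        }
        D = additive_matrix(true_splits, ids)
        best = None
        for splits in _five_taxon_topologies(ids):
            t = _tree_from_splits(ids, splits)
            fitted = ols_branch_lengths(t, D)
            resid = _residual(fitted, D)
            if best is None or resid < best[0]:
                best = (resid, splits)
        assert best[0] < 1e-18
        true_internal = {frozenset({"A", "B"}), frozenset({"D", "E"})}
        assert {s for s in best[1] if len(s) == 2} == true_internal
        wrong = _tree_from_splits(
            ids, {frozenset({"A", "C"}), frozenset({"D", "E"})}
        )
        refined = minimum_evolution_refine(wrong, D)
        recovered = {
            s if len(s) == 2 else frozenset(set(ids) - s)
            for s in tip_sets(refined)
        }
        assert recovered == true_internal

    def test_never_increases_tree_length(self, three_clade_sim):
        D = three_clade_sim["D"]
        nj = neighbor_joining(D)
        before = ols_branch_lengths(nj, D).total_length()
        refined = minimum_evolution_refine(nj, D)
        assert refined.total_length() <= before + 1e-9

    def test_rejects_nonbinary_tree(self):
        ids = ["A", "B", "C", "D"]
        star = PhylogeneticTree(ids)
        hub = star.new_node()
        for i in range(4):
            star.add_edge(hub, i, 0.1)
        with pytest.raises(TreeError, match="binary"):
            minimum_evolution_refine(star, quartet_matrix())


def _five_taxon_topologies(ids):
    """All 15 unrooted binary 5-taxon topologies as internal split pairs."""
    seen = []
    for pair1 in itertools.combinations(ids, 2):
        rest = [x for x in ids if x not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            key = {frozenset(pair1), frozenset(pair2)}
            if key not in seen:
                seen.append(key)
    return seen


def _tree_from_splits(ids, splits):
    t = PhylogeneticTree(ids)
    cherries = sorted(splits, key=sorted)
    (a1, a2), (b1, b2) = (sorted(s) for s in cherries)
    lone = next(x for x in ids if x not in {a1, a2, b1, b2})
    u, v, w = t.new_node(), t.new_node(), t.new_node()
    t.add_edge(u, ids.index(a1), 0.1)
    t.add_edge(u, ids.index(a2), 0.1)
    t.add_edge(v, ids.index(b1), 0.1)
    t.add_edge(v, ids.index(b2), 0.1)
    t.add_edge(w, ids.index(lone), 0.1)
    t.add_edge(u, w, 0.1)
    t.add_edge(v, w, 0.1)
    return t


class TestPropertyAdditive:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_instances_recovered(self, seed):
        from teclass.studies import _random_additive_case

        rng = np.random.default_rng(seed)
        true_tree, D = _random_additive_case(rng, 4 + seed % 3)
        tree = build_tree(D)
        assert tip_sets(tree) == tip_sets(true_tree)
        fitted, truth = split_lengths(tree), split_lengths(true_tree)
        for split, length in truth.items():
            assert fitted[split] == pytest.approx(length, abs=1e-9)


@pytest.fixture(scope="module")
def small_aln():
    spec = SequenceSimSpec(
        n_subfamilies=2, tips_per_subfamily=4, sites=150, seed=23
    )
    aln, truth, _ = simulate_subfamily_alignment(spec)
    return aln, truth


class TestBootstrap:
    def test_unanimous_stem_support(self, small_aln):
        aln, truth = small_aln
        tree = bootstrap_supports(aln, cfg=BootstrapConfig(20, seed=5))
        side = frozenset(
            i for i, l in enumerate(tree.tip_labels)
            if l in truth.groups["SF1"]
        )
        splits = tree.bipartitions()
        comp = frozenset(range(tree.n_tips)) - side
        eid = splits.get(side, splits.get(comp))
        assert eid is not None and tree.supports[eid] == 100.0

    def test_seed_determinism(self, small_aln):
        aln, _ = small_aln
        t1 = bootstrap_supports(aln, cfg=BootstrapConfig(10, seed=9))
        t2 = bootstrap_supports(aln, cfg=BootstrapConfig(10, seed=9))
        assert t1.newick() == t2.newick()

    def test_supports_match_hand_tally(self, small_aln):
        aln, _ = small_aln
        tree, reps = bootstrap_supports(
            aln, cfg=BootstrapConfig(20, seed=1), keep_replicates=True
        )
        assert len(reps) == 20
        for side, eid in tree.bipartitions().items():
            names = frozenset(tree.tip_labels[i] for i in side)
            count = 0
            for rep in reps:
                rep_sides = {
                    frozenset(rep.tip_labels[i] for i in s)
                    for s in rep.bipartitions()
                }
                rep_all = frozenset(rep.tip_labels)
                rep_sides |= {rep_all - s for s in rep_sides}
                count += names in rep_sides
            assert tree.supports[eid] == pytest.approx(100.0 * count / 20)

    def test_consensus_tree_writer(self, small_aln):
        aln, _ = small_aln
        _, reps = bootstrap_supports(
            aln, cfg=BootstrapConfig(10, seed=2), keep_replicates=True
        )
        nwk = majority_rule_consensus(reps)
        assert nwk.count("(") >= 1 and nwk.endswith(";")


class TestRooting:
    def test_single_tip_outgroup(self):
        D = quartet_matrix()
        tree = neighbor_joining(D)
        rooted = root_with_outgroup(tree, {"D"})
        assert rooted.root is not None
        kids = list(rooted.adj[rooted.root])
        assert any(
            k < rooted.n_tips and rooted.tip_labels[k] == "D" for k in kids
        )

    def test_complement_outgroup_gives_same_root_edge(self):
        D = quartet_matrix()
        tree = neighbor_joining(D)
        r1 = root_with_outgroup(tree, {"A", "B"})
        r2 = root_with_outgroup(tree, {"C", "D"})
        assert tip_sets(unroot(r1)) == tip_sets(unroot(r2)) == tip_sets(tree)

    def test_non_monophyletic_outgroup_rejected(self):
        ids = ["A", "B", "C", "D", "E"]
        splits = {
            frozenset({x}): 0.1 for x in ids
        } | {frozenset({"A", "B"}): 0.3, frozenset({"D", "E"}): 0.3}
        D = additive_matrix(splits, ids)
        tree = neighbor_joining(D)
        with pytest.raises(TreeError, match="monophyletic"):
            root_with_outgroup(tree, {"A", "D"})

    def test_bipartitions_invariant_under_root_unroot(self, three_clade_sim):
        tree = three_clade_sim["tree"]
        truth = three_clade_sim["truth"]
        rooted = root_with_outgroup(tree, truth.groups["SF1"])
        assert tip_sets(unroot(rooted)) == tip_sets(tree)


class TestNewick:
    def test_roundtrip_preserves_splits_lengths_supports(self, three_clade_sim):
        tree = three_clade_sim["tree"]
        again = PhylogeneticTree.from_newick(tree.newick())
        assert tip_sets(again) == tip_sets(tree)
        l1, l2 = split_lengths(tree), split_lengths(again)
        for split, length in l1.items():
            assert l2[split] == pytest.approx(length, abs=1e-9)
        all_tips = frozenset(tree.tip_labels)

        def support_map(t):
            return {
                _canonical(
                    frozenset(t.tip_labels[i] for i in s), all_tips
                ): t.supports.get(e)
                for s, e in t.bipartitions().items()
            }

        assert support_map(tree) == support_map(again)
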