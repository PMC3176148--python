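"""Validation studies: seeded simulation experiments for every stage.

Each function runs a self-contained experiment — simulate inputs with known
ground truth, push them through the package, measure the outcome — and
returns plain numbers.  The test suite asserts on these numbers and the
acceptance script reports them, so the studies double as the package's
reproducible validation protocol.

Problem sizes follow the synthetic study conditions (three subfamilies of
ten sequences at 300 aligned columns; three specificity classes of eight
enzymes) with bootstrap effort chosen per study; see the methods note.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from . import clustering, subfamilies, trees
from .datasets import characterized_te_profiles
from .errors import TEClassError
from .jtt import JTT, EvolutionaryDistanceMatrix, distance_matrix, pairwise_ml_distance
from .models import SpecificityClassifier
from .specificity import profiles_from_peak_tables
from .synthetic import (
    ProfileSimSpec,
    SequenceSimSpec,
    simulate_profiles,
    simulate_subfamily_alignment,
    species_map,
)


# ---------------------------------------------------------------------------
# Distance engine vs grid-search oracle
# ---------------------------------------------------------------------------

def grid_search_distance(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    grid: np.ndarray,
    model=JTT,
) -> float:
    """Exhaustive-grid ML distance for one pair (the independent oracle).

    Evaluates the pairwise log-likelihood on every grid point by direct
    spectral expansion and returns the argmax.  Deliberately independent
    of the bounded-optimization path used by ``pairwise_ml_distance``.
    """
    from .jtt import _pair_counts

    counts = _pair_counts(counts_a, counts_b)
    rows, cols = np.nonzero(counts)
    c = counts[rows, cols]
    log_pi = np.log(model.pi[rows])
    W = model._right[rows] * model._left[:, cols].T  # (m, 20) per-cell weights
    best_ll, best_t = -np.inf, grid[0]
    for chunk in np.array_split(grid, max(1, len(grid) // 5000)):
        E = np.exp(np.outer(model._eigvals, chunk))  # (20, T)
        P = W @ E  # (m, T)
        np.clip(P, 1e-300, None, out=P)
        ll = c @ (log_pi[:, None] + np.log(P))
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best_t = float(ll[i]), float(chunk[i])
    return best_t


def distance_oracle_study(
    n_pairs: int = 20,
    sites: int = 200,
    base_seed: int = 0,
    grid_step: float = 1e-4,
) -> dict:
    """Max |ML distance - grid argmax| over random simulated pairs."""
    rng = np.random.default_rng(base_seed)
    grid = np.arange(grid_step, 10.0 + grid_step / 2, grid_step)
    worst = 0.0
    for _ in range(n_pairs):
        t_true = float(rng.uniform(0.05, 2.0))
        a = rng.choice(20, size=sites, p=JTT.pi)
        P = JTT.transition_matrix(t_true)
        b = np.array([rng.choice(20, p=P[x]) for x in a])
        d_opt, _, _ = pairwise_ml_distance(a, b)
        d_grid = grid_search_distance(a, b, grid)
        worst = max(worst, abs(d_opt - d_grid))
    return {"max_abs_error": worst, "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# Tree oracle: additive matrices
# ---------------------------------------------------------------------------

def _random_additive_case(rng: np.random.Generator, n_taxa: int):
    """A random binary tree and its exact additive distance matrix."""
    spec_tree = trees.PhylogeneticTree([f"t{i}" for i in range(n_taxa)])
    # random binary unrooted topology by sequential tip insertion
    nodes = [0, 1, 2]
    center = spec_tree.new_node()
    for t in nodes:
        spec_tree.add_edge(center, t, 0.0)
    for tip in range(3, n_taxa):
        eid, _ = spec_tree.live_edges()[
            int(rng.integers(len(spec_tree.live_edges())))
        ]
        u, v = spec_tree.edges[eid]
        spec_tree.remove_edge(u, v)
        mid = spec_tree.new_node()
        spec_tree.add_edge(u, mid, 0.0)
        spec_tree.add_edge(mid, v, 0.0)
        spec_tree.add_edge(mid, tip, 0.0)
    for eid, _ in spec_tree.live_edges():
        spec_tree.lengths[eid] = float(rng.uniform(0.05, 0.6))
    # path-length matrix
    n = n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        # BFS accumulating path lengths
        dist = {i: 0.0}
        stack = [i]
        while stack:
            node = stack.pop()
            for nbr, eid in spec_tree.adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + spec_tree.lengths[eid]
                    stack.append(nbr)
        for j2 in range(n):
            D[i, j2] = dist[j2]
    np.fill_diagonal(D, 0.0)
    edm = EvolutionaryDistanceMatrix(
        spec_tree.tip_labels, D, np.zeros((n, n), dtype=int), {}
    )
    return spec_tree, edm


def tree_oracle_study(n_cases: int = 10, base_seed: int = 0) -> dict:
    """NJ+OLS on random additive 4-5 taxon matrices vs the generating tree.

    Measures the worst branch-length error (true topology recovered, OLS
    lengths equal the generating ones) and the worst ME length increase
    from refinement (must be <= 0 up to round-off).
    """
    rng = np.random.default_rng(base_seed)
    worst_bl = 0.0
    worst_increase = -math.inf
    for case in range(n_cases):
        n_taxa = 4 + case % 2
        true_tree, edm = _random_additive_case(rng, n_taxa)
        nj = trees.neighbor_joining(edm)
        if nj.bipartitions().keys() != true_tree.bipartitions().keys():
            worst_bl = math.inf
            continue
        fitted = trees.ols_branch_lengths(nj, edm)
        true_by_split = _lengths_by_split(true_tree)
        fit_by_split = _lengths_by_split(fitted)
        for split, length in true_by_split.items():
            worst_bl = max(worst_bl, abs(length - fit_by_split[split]))
        before = trees._ols_fit(
            nj, edm.d, list(range(n_taxa))
        )[2]
        refined = trees.minimum_evolution_refine(nj, edm)
        after = trees._ols_fit(
            refined, edm.d, [refined.tip_labels.index(l) for l in edm.ids]
        )[2]
        worst_increase = max(worst_increase, after - before)
    return {
        "max_branch_length_error": worst_bl,
        "max_me_length_increase": worst_increase,
        "n_cases": n_cases,
    }


def _lengths_by_split(tree: trees.PhylogeneticTree) -> dict:
    out = {}
    for eid, _ in tree.live_edges():
        out[tree.edge_side(eid)] = tree.lengths[eid]
    return out


# ---------------------------------------------------------------------------
# z-statistic toy oracle
# ---------------------------------------------------------------------------

def toy_z_matrix() -> EvolutionaryDistanceMatrix:
    """The 4+4 toy: intra distances cycle {0.08, 0.10, 0.12}, inter cycle
    {0.85, 0.90, 0.95}; deterministic assignment by pair order."""
    ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    d = np.zeros((8, 8))
    intra = itertools.cycle([0.08, 0.10, 0.12])
    inter = itertools.cycle([0.85, 0.90, 0.95])
    for i in range(8):
        for j in range(i + 1, 8):
            same = (i < 4) == (j < 4)
            d[i, j] = d[j, i] = next(intra) if same else next(inter)
    return EvolutionaryDistanceMatrix(ids, d, np.zeros((8, 8), int), {})


def toy_z_oracle(counts: str = "pairs") -> tuple[float, float]:
    """(package z, independently recomputed z) on the 4+4 toy matrix."""
    D = toy_z_matrix()
    A = {f"a{i}" for i in range(4)}
    B = {f"b{i}" for i in range(4)}
    rec = subfamilies.pair_statistics(D, A, B)
    z_pkg = subfamilies.z_value(rec, counts=counts, n_taxa=(4, 4))
    # direct arithmetic over the enumerated pairs, written independently
    ia = [D.index(x) for x in sorted(A)]
    ib = [D.index(x) for x in sorted(B)]
    cross = [D.d[i, j] for i in ia for j in ib]
    wa = [D.d[i, j] for i, j in itertools.combinations(ia, 2)]
    wb = [D.d[i, j] for i, j in itertools.combinations(ib, 2)]
    mean = lambda v: sum(v) / len(v)
    var = lambda v: mean([(x - mean(v)) ** 2 for x in v])
    d_inter, v_inter = mean(cross), var(cross)
    n_intra = len(wa) + len(wb)
    d_intra = (sum(wa) + sum(wb)) / n_intra
    v_intra = (len(wa) * var(wa) + len(wb) * var(wb)) / n_intra
    if counts == "pairs":
        n1, n2 = len(cross), n_intra
    else:
        n1 = n2 = len(ia) + len(ib)
    z_direct = (d_inter - d_intra) / math.sqrt(v_inter / n1 + v_intra / n2)
    return z_pkg, z_direct


# ---------------------------------------------------------------------------
# Subfamily parameter recovery and null calibration
# ---------------------------------------------------------------------------

def subfamily_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    bootstrap_replicates: int = 25,
    z_threshold: float = 3.3,
) -> dict:
    """Exact partition recovery rate on three-subfamily simulations.

    Per seed: simulate (3 clades x 10 tips, 300 sites, intra depth 0.1,
    stem 1.0), run distances -> bootstrap tree -> propose -> refine, and
    score success when the recovered groups equal the generating ones and
    every pairwise z clears the threshold.
    """
    successes = 0
    min_z_values = []
    for s in range(n_seeds):
        spec = SequenceSimSpec(seed=base_seed * 1009 + 17 * s)
        aln, truth, _ = simulate_subfamily_alignment(spec)
        D = distance_matrix(aln)
        tree = trees.bootstrap_supports(
            aln,
            cfg=trees.BootstrapConfig(bootstrap_replicates, spec.seed + 3),
        )
        sp = species_map(aln)
        initial = subfamilies.propose_initial_partition(tree, species_of=sp)
        try:
            final, _log = subfamilies.refine_partition(
                D, tree, initial, z_threshold, species_of=sp
            )
        except TEClassError:
            min_z_values.append(float("nan"))
            continue
        report = subfamilies.validate_partition(
            D, final, z_threshold, species_of=sp
        )
        truth_sets = {frozenset(v) for v in truth.groups.values()}
        final_sets = {frozenset(v) for v in final.groups.values()}
        ok = report.passed and truth_sets == final_sets
        successes += ok
        min_z_values.append(report.min_z())
    return {
        "recovery_fraction": successes / n_seeds,
        "min_z_median": float(np.nanmedian(min_z_values)),
        "n_seeds": n_seeds,
    }


def null_split_study(
    n_replicates: int = 200,
    base_seed: int = 0,
    z_threshold: float = 3.3,
) -> dict:
    """Calibration: z for an arbitrary split of one homogeneous clade.

    Simulates a single 10-tip clade (300 sites, intra depth 0.1), splits
    it into two fixed halves, and records how often z stays below the
    acceptance threshold — the rule should rarely certify a split with no
    underlying structure.
    """
    below = 0
    zs = []
    for r in range(n_replicates):
        spec = SequenceSimSpec(
            n_subfamilies=1, seed=base_seed * 2003 + 13 * r
        )
        aln, truth, _ = simulate_subfamily_alignment(spec)
        D = distance_matrix(aln)
        ids = sorted(truth.groups["SF1"])
        A, B = set(ids[:5]), set(ids[5:])
        rec = subfamilies.pair_statistics(D, A, B)
        z = subfamilies.z_value(rec)
        zs.append(z)
        below += z < z_threshold
    return {
        "fraction_below_threshold": below / n_replicates,
        "z_median": float(np.median(zs)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Specificity pipeline inversion
# ---------------------------------------------------------------------------

def inversion_study(base_seed: int = 0) -> dict:
    """Noise-free peak tables -> pipeline -> mol% round-trip error."""
    spec = ProfileSimSpec(
        dirichlet_concentration=None,
        control_background={},
        seed=base_seed,
    )
    sim = simulate_profiles(spec)
    profiles = profiles_from_peak_tables(sim.peak_tables, {}, sim.standards)
    worst = 0.0
    worst_sum = 0.0
    for p in profiles:
        truth = sim.true_molpct[p.enzyme_id]
        for s, v in truth.items():
            worst = max(worst, abs(p.mol_percent.get(s, 0.0) - v))
        worst_sum = max(worst_sum, abs(sum(p.mol_percent.values()) - 100.0))
    return {
        "max_molpct_error": worst,
        "max_molpct_sum_deviation": worst_sum,
        "n_profiles": len(profiles),
    }


# ---------------------------------------------------------------------------
# Class recovery and the printed-values fixture
# ---------------------------------------------------------------------------

def _labels_match(pred: dict[str, int], truth: dict[str, str]) -> bool:
    """Predicted integer labels equal truth up to permutation."""
    mapping: dict[int, str] = {}
    for enzyme, lab in pred.items():
        t = truth[enzyme]
        if mapping.setdefault(lab, t) != t:
            return False
    return len(set(mapping.values())) == len(set(truth.values()))


def class_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    replicates: int = 1000,
) -> dict:
    """Three-archetype recovery rate and AU support at the class nodes."""
    matches = 0
    class_node_au: list[float] = []
    for s in range(n_seeds):
        spec = ProfileSimSpec(seed=base_seed * 4001 + 29 * s)
        sim = simulate_profiles(spec)
        classifier = SpecificityClassifier.from_peak_tables(
            sim.peak_tables, dict(spec.control_background), sim.standards
        )
        results = classifier.fit(
            k=3, replicates=replicates, seed=base_seed * 7 + s
        )
        matches += _labels_match(results.class_labels, sim.true_labels)
        dend = results.dendrogram
        leafsets = dend.node_leafsets()
        truth_sets = {}
        for enzyme, cls in sim.true_labels.items():
            truth_sets.setdefault(cls, set()).add(enzyme)
        for cls, members in truth_sets.items():
            fs = frozenset(members)
            found = [
                dend.n + t for t, ls in enumerate(leafsets) if ls == fs
            ]
            class_node_au.append(
                dend.au[found[0]] if found else 0.0
            )
    return {
        "recovery_fraction": matches / n_seeds,
        "median_class_node_au": float(np.median(class_node_au)),
        "n_seeds": n_seeds,
    }


def fixture_classification() -> dict:
    """k=3 cut of the printed-values fixture: do the C8-dominant and the
    C14/C16-dominant enzymes land in separate classes?"""
    subset = [
        "Cuphea_palustris",
        "CvFatB1",
        "CvFatB3",
        "Elaeis_guineensis",
        "Anaerococcus_tetradius",
    ]
    frame = characterized_te_profiles(subset)
    classifier = SpecificityClassifier.from_molpct_frame(frame)
    results = classifier.fit(k=3, replicates=100, seed=0)
    labels = results.class_labels
    c8 = {"Cuphea_palustris", "Anaerococcus_tetradius"}
    c14 = {"CvFatB3", "Elaeis_guineensis"}
    ok = (
        len({labels[e] for e in c8}) == 1
        and len({labels[e] for e in c14}) == 1
        and {labels[e] for e in c8}.isdisjoint({labels[e] for e in c14})
    )
    return {"separation_ok": float(ok), "labels": labels, "n_enzymes": len(subset)}


def threshold_probability() -> dict:
    """Upper-tail normal probabilities at the z acceptance threshold."""
    from scipy.stats import norm

    one_sided = float(norm.sf(3.3))
    return {
        "one_sided_p": one_sided,
        "two_sided_p": 2.0 * one_sided,
    }
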