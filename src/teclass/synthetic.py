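"""Seeded generators of synthetic study inputs.

Two families of generators mirror the statistical structure the analysis
assumes:

* sequence side — subfamily-structured protein alignments: k clades of
  random (coalescent-shaped, non-ultrametric) subtrees with tight
  within-clade divergence joined by long stems, evolved site-wise under the
  JTT process, giving tight intra-clade and wide inter-clade distances;
* specificity side — fatty-acid composition vectors drawn around class
  archetypes with Dirichlet noise, lognormal total production, the control
  strain's background, and internal-standard peak tables produced by
  inverting the quantitation arithmetic, so the full pipeline can be
  exercised end to end.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import AMINO_ACIDS, AlignedProteinSet, ProteinRecord
from .errors import TEClassError
from .jtt import JTT, SubstitutionModel
from .specificity import AnalytePeak, InternalStandardSet, is_fatty_acid
from .subfamilies import SubfamilyPartition
from .trees import PhylogeneticTree


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

@dataclass
class SequenceSimSpec:
    """Study conditions for subfamily-structured alignments.

    ``intra_depth`` is the scale of within-clade root-to-tip divergence
    (each tip depth is drawn uniformly in [0.5, 1.0] x intra_depth,
    substitutions/site); ``stem_length`` separates the clades.
    """

    n_subfamilies: int = 3
    tips_per_subfamily: int = 10
    intra_depth: float = 0.1
    stem_length: float = 1.0
    sites: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subfamilies < 1 or self.tips_per_subfamily < 2:
            raise TEClassError("need k >= 1 subfamilies with >= 2 tips each")
        if self.sites < 1 or self.intra_depth < 0 or self.stem_length < 0:
            raise TEClassError("sites >= 1 and non-negative depths required")


def _random_clade(
    tree: PhylogeneticTree,
    tips: list[int],
    depth_scale: float,
    rng: np.random.Generator,
) -> int:
    """Attach a random nested (coalescent-shaped) subtree over ``tips``.

    Returns the clade root node.  Tip depths below the clade root are
    drawn ~ U(0.5, 1.0) * depth_scale; internal nodes sit at a random
    fraction of the shallowest descendant's target depth, keeping every
    branch length positive.
    """
    targets = {t: depth_scale * rng.uniform(0.5, 1.0) for t in tips}

    def build(subset: list[int], top_depth: float) -> tuple[int, float]:
        # returns (node, node depth)
        if len(subset) == 1:
            return subset[0], targets[subset[0]]
        k = int(rng.integers(1, len(subset)))
        left, right = subset[:k], subset[k:]
        node = tree.new_node()
        floor = min(targets[t] for t in subset)
        depth = top_depth + rng.uniform(0.2, 0.8) * (floor - top_depth)
        for part in (left, right):
            child, child_depth = build(part, depth)
            tree.add_edge(node, child, child_depth - depth)
        return node, depth

    shuffled = list(tips)
    rng.shuffle(shuffled)
    root, _ = build(shuffled, 0.0)
    return root


def simulate_tree(
    spec: SequenceSimSpec,
) -> tuple[PhylogeneticTree, SubfamilyPartition]:
    """A k-clade tree plus the generating (true) subfamily partition."""
    rng = np.random.default_rng(spec.seed)
    k, m = spec.n_subfamilies, spec.tips_per_subfamily
    labels = [f"SF{c + 1}_t{i + 1}" for c in range(k) for i in range(m)]
    tree = PhylogeneticTree(labels)
    clade_roots = []
    for c in range(k):
        tips = list(range(c * m, (c + 1) * m))
        clade_roots.append(
            _random_clade(tree, tips, spec.intra_depth, rng)
        )
    if k == 1:
        pass
    elif k == 2:
        tree.add_edge(clade_roots[0], clade_roots[1], 2.0 * spec.stem_length)
    else:
        hub = tree.new_node()
        for r in clade_roots:
            tree.add_edge(hub, r, spec.stem_length)
    groups = {
        f"SF{c + 1}": {f"SF{c + 1}_t{i + 1}" for i in range(m)}
        for c in range(k)
    }
    return tree, SubfamilyPartition(groups)


def species_map(aln_or_tree) -> dict[str, str]:
    """id -> species map; simulated tips get one distinct species each."""
    if isinstance(aln_or_tree, AlignedProteinSet):
        return {r.id: r.species for r in aln_or_tree.records}
    return {
        lbl: f"species_{lbl}" for lbl in aln_or_tree.tip_labels
    }


def simulate_alignment(
    tree: PhylogeneticTree,
    sites: int,
    model: SubstitutionModel = JTT,
    seed: int = 0,
) -> AlignedProteinSet:
    """Evolve an alignment along the tree under the substitution model.

    Root states are drawn from the stationary frequencies; every branch
    transforms states site-wise by sampling from the rows of P(branch
    length).  Tips receive distinct species labels.
    """
    rng = np.random.default_rng(seed)
    start = next(
        (n for n in tree.adj if tree.adj[n] and n >= tree.n_tips), 0
    )
    states: dict[int, np.ndarray] = {
        start: rng.choice(20, size=sites, p=model.pi)
    }
    seqs: dict[int, np.ndarray] = {}
    stack = [(start, None)]
    while stack:
        node, parent = stack.pop()
        if node < tree.n_tips:
            seqs[node] = states[node]
        for child in tree.adj[node]:
            if child == parent:
                continue
            eid = tree.adj[node][child]
            P = model.transition_matrix(tree.lengths[eid])
            parent_states = states[node]
            child_states = np.empty(sites, dtype=np.int64)
            for a in range(20):
                mask = parent_states == a
                cnt = int(mask.sum())
                if cnt:
                    child_states[mask] = rng.choice(20, size=cnt, p=P[a])
            states[child] = child_states
            stack.append((child, node))
        del states[node]
    records = [
        ProteinRecord(
            lbl,
            f"species_{lbl}",
            "".join(AMINO_ACIDS[s] for s in seqs[i]),
        )
        for i, lbl in enumerate(tree.tip_labels)
    ]
    return AlignedProteinSet(records)


def simulate_subfamily_alignment(
    spec: SequenceSimSpec,
) -> tuple[AlignedProteinSet, SubfamilyPartition, PhylogeneticTree]:
    """Convenience: tree + alignment + truth in one seeded call."""
    tree, truth = simulate_tree(spec)
    aln = simulate_alignment(tree, spec.sites, seed=spec.seed + 1)
    return aln, truth, tree


# ---------------------------------------------------------------------------
# Specificity-profile simulation
# ---------------------------------------------------------------------------

#: Fatty-acid species universe for simulated compositions.
FA_UNIVERSE = (
    "4:0", "6:0", "8:0", "10:0", "12:0", "14:0", "14:1", "16:0", "16:1",
    "18:0", "18:1",
)

#: Three class archetypes (mol%, summing to 100): a long-chain
#: C14/C16-dominant class, a bimodal C8 + C14 class, and a C8-dominant
#: class — the composition structure observed across characterized
#: thioesterases.
CLASS_ARCHETYPES: dict[str, dict[str, float]] = {
    "I": {
        "14:0": 45.0, "16:0": 20.0, "16:1": 30.0,
        "12:0": 2.0, "14:1": 2.0, "18:1": 1.0,
    },
    "II": {
        "8:0": 35.0, "14:0": 30.0, "12:0": 15.0,
        "6:0": 5.0, "10:0": 5.0, "14:1": 4.0, "16:0": 3.0, "16:1": 3.0,
    },
    "III": {
        "8:0": 80.0, "6:0": 10.0,
        "4:0": 4.0, "10:0": 4.0, "12:0": 1.0, "14:0": 1.0,
    },
}

#: Control-strain background (nmol/mL): the three most abundant fatty
#: acids of the empty-plasmid strain.
CONTROL_BACKGROUND: dict[str, float] = {"8:0": 2.0, "14:0": 3.5, "16:0": 3.1}


@dataclass
class ProfileSimSpec:
    """Study conditions for synthetic specificity profiles."""

    archetypes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in CLASS_ARCHETYPES.items()
        }
    )
    profiles_per_class: int = 8
    dirichlet_concentration: float | None = 200.0
    total_fa_log_mu: float = float(np.log(200.0))
    total_fa_log_sigma: float = 0.8
    control_background: dict[str, float] = field(
        default_factory=lambda: dict(CONTROL_BACKGROUND)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, arch in self.archetypes.items():
            total = sum(arch.values())
            if abs(total - 100.0) > 1e-6:
                raise TEClassError(
                    f"archetype {name!r} mol% sums to {total}, expected 100"
                )
        if (
            self.dirichlet_concentration is not None
            and self.dirichlet_concentration <= 0
        ):
            raise TEClassError("Dirichlet concentration must be positive")


@dataclass
class SimulatedProfiles:
    """Ground truth plus the raw tables the pipeline consumes."""

    true_labels: dict[str, str]              # enzyme -> archetype name
    true_molpct: dict[str, dict[str, float]]
    peak_tables: dict[str, list[AnalytePeak]]
    control_peaks: list[AnalytePeak]
    standards: InternalStandardSet

    def peaks_frame(self) -> pd.DataFrame:
        rows = [
            {"enzyme": e, "species": p.species, "area": p.area}
            for e in sorted(self.peak_tables)
            for p in self.peak_tables[e]
        ]
        return pd.DataFrame(rows)

    def control_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"enzyme": "control", "species": p.species, "area": p.area}
                for p in self.control_peaks
            ]
        )


#: Fixed detector response used when emitting synthetic peak tables; the
#: absolute value is arbitrary since quantitation is ratio-based.
_IS_PEAK_AREA = 1.0e4


def _peaks_from_concentrations(
    conc: dict[str, float], standards: InternalStandardSet
) -> list[AnalytePeak]:
    """Invert the quantitation arithmetic: concentrations -> peak areas."""
    peaks = [
        AnalytePeak(std, _IS_PEAK_AREA) for std in standards.standards
    ]
    for species, value in sorted(conc.items()):
        std = standards.assign(species)
        area = value / standards.concentration(std) * _IS_PEAK_AREA
        peaks.append(AnalytePeak(species, area))
    return peaks


def simulate_profiles(spec: ProfileSimSpec) -> SimulatedProfiles:
    """Synthetic per-enzyme peak tables around the class archetypes.

    Per enzyme: mol% ~ Dirichlet(concentration x archetype / 100) (the
    archetype itself when concentration is None), total fatty acid
    ~ lognormal, net concentrations = mol% x total / 100, raw
    concentrations = net + control background, and peak areas by inverting
    the internal-standard arithmetic.
    """
    rng = np.random.default_rng(spec.seed)
    standards = InternalStandardSet()
    true_labels: dict[str, str] = {}
    true_molpct: dict[str, dict[str, float]] = {}
    peak_tables: dict[str, list[AnalytePeak]] = {}
    for cls in sorted(spec.archetypes):
        arch = spec.archetypes[cls]
        species = sorted(arch, key=lambda s: (len(s), s))
        alpha = np.array([arch[s] for s in species])
        for i in range(spec.profiles_per_class):
            enzyme = f"class{cls}_e{i + 1}"
            if spec.dirichlet_concentration is None:
                molpct = alpha / alpha.sum() * 100.0
            else:
                molpct = 100.0 * rng.dirichlet(
                    spec.dirichlet_concentration * alpha / 100.0
                )
            total = float(
                np.exp(
                    rng.normal(spec.total_fa_log_mu, spec.total_fa_log_sigma)
                )
            )
            net = {s: molpct[k] * total / 100.0 for k, s in enumerate(species)}
            raw = dict(net)
            for s, bg in spec.control_background.items():
                raw[s] = raw.get(s, 0.0) + bg
            true_labels[enzyme] = cls
            true_molpct[enzyme] = {
                s: float(molpct[k]) for k, s in enumerate(species)
            }
            peak_tables[enzyme] = _peaks_from_concentrations(raw, standards)
    control_peaks = _peaks_from_concentrations(
        dict(spec.control_background), standards
    )
    return SimulatedProfiles(
        true_labels, true_molpct, peak_tables, control_peaks, standards
    )
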