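"""Subfamily delineation by the pairwise z-statistic.

A candidate partition of the aligned sequences into subfamilies is accepted
when, for every pair of subfamilies, the mean inter-group evolutionary
distance exceeds the pooled mean intra-group distance by a statistically
significant margin.  The test statistic is the two-sample z

    z = (d_inter - d_intra) / sqrt(var_inter / N_inter + var_intra / N_intra)

where d_inter and var_inter are the mean and variance of the cross-group
pairwise distances, d_intra and var_intra pool the two within-group pair
sets (weighted by pair counts), and the N's follow a configurable count
convention (``counts="pairs"`` — the number of distances entering each mean,
the default — or ``counts="taxa"`` — the number of sequences involved).
z > 3.3 corresponds to p < 0.001 (one-sided upper tail ~ 4.83e-4).

A subfamily must additionally satisfy a membership rule: at least
``min_size`` sequences, from at least ``min_species`` distinct species.
Partitions failing either rule are refined by a deterministic greedy loop
that merges the worst-separated pair when their union is a clade of the
guide tree, and otherwise ejects the single sequence whose removal most
improves the minimum z, until the partition validates (some sequences may
end up non-grouped).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import PartitionError
from .jtt import EvolutionaryDistanceMatrix
from .trees import PhylogeneticTree

Z_THRESHOLD_DEFAULT = 3.3
MIN_SIZE_DEFAULT = 5


@dataclass
class SubfamilyPartition:
    """Disjoint subfamily groups plus the non-grouped remainder."""

    groups: dict[str, set[str]]
    non_grouped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            overlap = seen & members
            if overlap:
                raise PartitionError(
                    f"groups overlap on {sorted(overlap)} (group {label!r})"
                )
            seen |= members
        if seen & self.non_grouped:
            raise PartitionError(
                "sequences appear both grouped and non-grouped: "
                f"{sorted(seen & self.non_grouped)}"
            )

    @property
    def all_ids(self) -> set[str]:
        ids = set(self.non_grouped)
        for members in self.groups.values():
            ids |= members
        return ids

    def copy(self) -> "SubfamilyPartition":
        return SubfamilyPartition(
            {k: set(v) for k, v in self.groups.items()}, set(self.non_grouped)
        )

    def to_tsv(self, path) -> None:
        rows = []
        for label, members in sorted(self.groups.items()):
            rows += [(m, label) for m in sorted(members)]
        rows += [(m, "NA") for m in sorted(self.non_grouped)]
        with open(path, "w") as fh:
            fh.write("id\tgroup\n")
            for m, g in rows:
                fh.write(f"{m}\t{g}\n")


@dataclass
class ZTestRecord:
    """Per-pair distance statistics and the resulting z."""

    group_i: str
    group_j: str
    d_inter: float
    d_ii: float
    d_jj: float
    d_intra_pooled: float
    var_inter: float
    var_intra_pooled: float
    n_ij: int
    n_ii: int
    n_jj: int
    z: float | None = None
    degenerate: bool = False


def _pair_values(mat: np.ndarray, idx: list[int]) -> np.ndarray:
    sub = mat[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), 1)
    return sub[iu]


def pair_statistics(
    D: EvolutionaryDistanceMatrix,
    A: set[str],
    B: set[str],
    labels: tuple[str, str] = ("A", "B"),
    pooled_ddof: int = 0,
) -> ZTestRecord:
    """Inter/intra distance means and variances for two candidate groups.

    Variances are population variances by default (``pooled_ddof=0``); the
    pooled intra mean and variance weight the two within-group pair sets by
    their pair counts.  Groups must be disjoint with >= 2 members each.
    """
    if A & B:
        raise PartitionError(f"groups overlap on {sorted(A & B)}")
    if len(A) < 2 or len(B) < 2:
        raise PartitionError("each group needs >= 2 members for statistics")
    ia = [D.index(x) for x in sorted(A)]
    ib = [D.index(x) for x in sorted(B)]
    cross = D.d[np.ix_(ia, ib)].ravel()
    within_a = _pair_values(D.d, ia)
    within_b = _pair_values(D.d, ib)
    n_ij = cross.size
    n_ii = within_a.size
    n_jj = within_b.size
    d_inter = float(cross.mean())
    d_ii = float(within_a.mean())
    d_jj = float(within_b.mean())
    d_intra = (n_ii * d_ii + n_jj * d_jj) / (n_ii + n_jj)
    var_inter = float(cross.var(ddof=pooled_ddof)) if n_ij > pooled_ddof else 0.0
    # pair-count-weighted pooling of the two within-group variances
    va = float(within_a.var(ddof=pooled_ddof)) if n_ii > pooled_ddof else 0.0
    vb = float(within_b.var(ddof=pooled_ddof)) if n_jj > pooled_ddof else 0.0
    var_intra = (n_ii * va + n_jj * vb) / (n_ii + n_jj)
    # snap rounding dust on constant blocks to an exact zero so the
    # degenerate-separation path triggers deterministically
    if var_inter < 1e-30:
        var_inter = 0.0
    if var_intra < 1e-30:
        var_intra = 0.0
    return ZTestRecord(
        labels[0], labels[1], d_inter, d_ii, d_jj, d_intra,
        var_inter, var_intra, n_ij, n_ii, n_jj,
    )


def z_value(
    rec: ZTestRecord,
    counts: str = "pairs",
    n_taxa: tuple[int, int] | None = None,
) -> float:
    """Fill in and return the z statistic for a :class:`ZTestRecord`.

    ``counts="pairs"`` divides each variance by the number of distances
    entering the corresponding mean; ``counts="taxa"`` divides by the number
    of sequences involved (requires ``n_taxa=(|A|, |B|)``).  When both
    variances vanish, z is +inf (flagged degenerate) if the inter mean
    exceeds the pooled intra mean, and 0 on exact equality.
    """
    if counts == "pairs":
        n_inter, n_intra = rec.n_ij, rec.n_ii + rec.n_jj
    elif counts == "taxa":
        if n_taxa is None:
            # invert pair counts: n_ii = a(a-1)/2 etc.
            a = int(round((1 + math.sqrt(1 + 8 * rec.n_ii)) / 2))
            b = int(round((1 + math.sqrt(1 + 8 * rec.n_jj)) / 2))
        else:
            a, b = n_taxa
        n_inter, n_intra = a + b, a + b
    else:
        raise PartitionError(f"unknown count convention {counts!r}")
    denom_sq = rec.var_inter / n_inter + rec.var_intra_pooled / n_intra
    diff = rec.d_inter - rec.d_intra_pooled
    if denom_sq <= 0.0:
        if abs(diff) < 1e-15:
            rec.z = 0.0
        else:
            rec.z = math.inf if diff > 0 else -math.inf
            rec.degenerate = True
    else:
        rec.z = diff / math.sqrt(denom_sq)
    return rec.z


@dataclass
class ValidationReport:
    records: list[ZTestRecord]
    violations: list[str]
    passed: bool

    def min_z(self) -> float:
        zs = [r.z for r in self.records if r.z is not None]
        return min(zs) if zs else math.inf

    def to_json(self, path=None) -> str:
        payload = {
            "passed": self.passed,
            "violations": self.violations,
            "records": [asdict(r) for r in self.records],
        }

        def default(o):
            if isinstance(o, float) and math.isinf(o):
                return "inf"
            raise TypeError(o)

        text = json.dumps(payload, indent=2, default=default)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def count_species(members: set[str], species_of: dict[str, str]) -> int:
    return len({species_of.get(m, m) for m in members})


def membership_violations(
    partition: SubfamilyPartition,
    species_of: dict[str, str] | None,
    min_size: int,
    min_species: int | None,
) -> list[str]:
    """Check the subfamily membership rule for every group.

    The rule: at least ``min_size`` sequences from at least ``min_species``
    distinct species (strict reading; ``min_species`` defaults to
    ``min_size`` and is ignored when no species map is available).
    """
    return [
        msg for _label, msg in _membership_failures(
            partition, species_of, min_size, min_species
        )
    ]


def _membership_failures(
    partition: SubfamilyPartition,
    species_of: dict[str, str] | None,
    min_size: int,
    min_species: int | None,
) -> list[tuple[str, str]]:
    if min_species is None:
        min_species = min_size
    out = []
    for label, members in sorted(partition.groups.items()):
        if len(members) < min_size:
            out.append(
                (label,
                 f"group {label!r} has {len(members)} sequences "
                 f"(< {min_size})")
            )
        elif species_of is not None:
            n_sp = count_species(members, species_of)
            if n_sp < min_species:
                out.append(
                    (label,
                     f"group {label!r} spans {n_sp} species "
                     f"(< {min_species})")
                )
    return out


def validate_partition(
    D: EvolutionaryDistanceMatrix,
    partition: SubfamilyPartition,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    min_size: int = MIN_SIZE_DEFAULT,
    species_of: dict[str, str] | None = None,
    min_species: int | None = None,
    counts: str = "pairs",
) -> ValidationReport:
    """Audit a partition against the z and membership rules.

    Fails iff any pairwise z <= threshold or any group violates the
    membership rule; every pairwise record is returned for audit.
    """
    labels = sorted(partition.groups)
    records = []
    violations = membership_violations(
        partition, species_of, min_size, min_species
    )
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            rec = pair_statistics(
                D, partition.groups[gi], partition.groups[gj], (gi, gj)
            )
            z = z_value(
                rec,
                counts=counts,
                n_taxa=(len(partition.groups[gi]), len(partition.groups[gj])),
            )
            records.append(rec)
            if not z > z_threshold:
                violations.append(
                    f"z({gi},{gj}) = {z:.3f} <= {z_threshold}"
                )
    return ValidationReport(records, violations, passed=not violations)


# ---------------------------------------------------------------------------
# Initial proposal from a supported tree
# ---------------------------------------------------------------------------

def propose_initial_partition(
    tree: PhylogeneticTree,
    support_min: float = 70.0,
    min_size: int = MIN_SIZE_DEFAULT,
    species_of: dict[str, str] | None = None,
    min_species: int | None = None,
) -> SubfamilyPartition:
    """Apparent subfamilies from well-supported clades of the guide tree.

    An unrooted clade is identified with the minority side of a supported
    internal edge (both sides when the split is exactly even).  Candidates
    meeting the membership rule are accepted greedily from largest to
    smallest, skipping any that overlap an accepted clade, so nested
    qualifying clades resolve to the outermost one.  Remaining tips are
    non-grouped.
    """
    if min_species is None:
        min_species = min_size
    n = tree.n_tips
    all_tips = frozenset(range(n))
    candidates: set[frozenset[int]] = set()
    for side, eid in tree.bipartitions().items():
        if tree.supports.get(eid, 0.0) < support_min:
            continue
        comp = all_tips - side
        for s in (side, comp):
            if len(s) <= n // 2 and len(s) < n:
                candidates.add(s)
    label_of = tree.tip_labels

    def qualifies(s: frozenset[int]) -> bool:
        if len(s) < min_size:
            return False
        if species_of is not None:
            members = {label_of[i] for i in s}
            if count_species(members, species_of) < min_species:
                return False
        return True

    accepted: list[frozenset[int]] = []
    for cand in sorted(
        (c for c in candidates if qualifies(c)),
        key=lambda s: (-len(s), sorted(s)),
    ):
        if all(not (cand & a) for a in accepted):
            accepted.append(cand)
    groups = {
        f"SF{k + 1}": {label_of[i] for i in s}
        for k, s in enumerate(
            sorted(accepted, key=lambda s: (-len(s), sorted(s)))
        )
    }
    grouped = set().union(*groups.values()) if groups else set()
    non_grouped = set(label_of) - grouped
    return SubfamilyPartition(groups, non_grouped)


# ---------------------------------------------------------------------------
# Iterative refinement
# ---------------------------------------------------------------------------

def _min_z(
    D, partition: SubfamilyPartition, counts: str
) -> tuple[float, tuple[str, str] | None]:
    labels = sorted(partition.groups)
    worst = (math.inf, None)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            rec = pair_statistics(
                D, partition.groups[gi], partition.groups[gj], (gi, gj)
            )
            z = z_value(
                rec,
                counts=counts,
                n_taxa=(len(partition.groups[gi]), len(partition.groups[gj])),
            )
            if z < worst[0]:
                worst = (z, (gi, gj))
    return worst


def refine_partition(
    D: EvolutionaryDistanceMatrix,
    tree: PhylogeneticTree,
    initial: SubfamilyPartition,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    min_size: int = MIN_SIZE_DEFAULT,
    species_of: dict[str, str] | None = None,
    min_species: int | None = None,
    counts: str = "pairs",
) -> tuple[SubfamilyPartition, list[str]]:
    """Deterministic greedy refinement until the partition validates.

    While validation fails: dissolve groups violating the membership rule;
    then, for the worst-separated pair, merge the two groups if their union
    is a clade of the guide tree, otherwise eject (to non-grouped) the
    single member of that pair whose removal maximally increases the
    minimum z, breaking ties by lexicographically smallest id.  The loop is
    capped at ``10 * j`` iterations; on hitting the cap a
    :class:`PartitionError` carrying the best partition found is raised.
    Every action is recorded in the returned audit log.
    """
    part = initial.copy()
    log: list[str] = []
    clades = tree.clade_sets()
    cap = 10 * D.size
    best: tuple[float, SubfamilyPartition] = (-math.inf, part.copy())
    for _ in range(cap):
        # membership rule first: dissolve undersized groups
        bad = _membership_failures(part, species_of, min_size, min_species)
        dissolved = False
        for label, msg in bad:
            members = part.groups.pop(label)
            part.non_grouped |= members
            log.append(f"dissolve {label}: {msg}")
            dissolved = True
        if dissolved:
            continue
        if len(part.groups) < 2:
            report = validate_partition(
                D, part, z_threshold, min_size, species_of, min_species,
                counts,
            )
            if report.passed:
                return part, log
            raise PartitionError(
                "refinement collapsed below two groups without validating: "
                + "; ".join(report.violations)
            )
        worst_z, worst_pair = _min_z(D, part, counts)
        if worst_z > best[0]:
            best = (worst_z, part.copy())
        if worst_z > z_threshold:
            return part, log
        gi, gj = worst_pair
        union = part.groups[gi] | part.groups[gj]
        if frozenset(union) in clades:
            part.groups[gi] = union
            del part.groups[gj]
            log.append(
                f"merge {gj} into {gi} (z = {worst_z:.3f}, union is a clade)"
            )
            continue
        # eject the member whose removal maximally increases the minimum z
        best_eject: tuple[float, str, str] | None = None
        for label in (gi, gj):
            if len(part.groups[label]) <= 2:
                continue
            for member in sorted(part.groups[label]):
                trial = part.copy()
                trial.groups[label].discard(member)
                trial.non_grouped.add(member)
                trial_z, _ = _min_z(D, trial, counts)
                key = (trial_z, member, label)
                if best_eject is None or trial_z > best_eject[0] or (
                    trial_z == best_eject[0] and member < best_eject[1]
                ):
                    best_eject = key
        if best_eject is None:
            raise PartitionError(
                f"cannot refine: worst pair ({gi},{gj}) has z = "
                f"{worst_z:.3f} but no sequence can be ejected"
            )
        _, member, label = best_eject
        part.groups[label].discard(member)
        part.non_grouped.add(member)
        log.append(
            f"eject {member} from {label} "
            f"(worst z({gi},{gj}) = {worst_z:.3f})"
        )
    raise PartitionError(
        f"refinement did not converge within {cap} iterations; best minimum "
        f"z reached was {best[0]:.3f}"
    )
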