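"""Model/Results front end for the two analyses.

Mirrors the fit-object idiom of statistical modelling packages: a model
object is built from data, ``fit()`` runs the procedure, and the returned
results object carries the estimates, their uncertainties (bootstrap
supports, z-statistics, AU p-values) and a ``summary()`` table.

* :class:`SubfamilyModel` — from a protein MSA to a validated subfamily
  partition (JTT distances -> NJ + minimum-evolution tree -> bootstrap ->
  z-test refinement).
* :class:`SpecificityClassifier` — from fatty-acid measurements to
  substrate-specificity classes (internal-standard quantitation ->
  background subtraction -> mol% -> Ward clustering with multiscale
  bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, specificity, subfamilies, trees
from .alignio import AlignedProteinSet, read_msa
from .jtt import JTT, EvolutionaryDistanceMatrix, SubstitutionModel, distance_matrix
from .subfamilies import SubfamilyPartition, ValidationReport


class SubfamilyModel:
    """Phylogeny-guided delineation of protein subfamilies from an MSA.

    Parameters
    ----------
    alignment : AlignedProteinSet
        The aligned catalytic domains with species metadata.
    substitution_model : SubstitutionModel, optional
        Defaults to JTT-1992.
    """

    def __init__(
        self,
        alignment: AlignedProteinSet,
        substitution_model: SubstitutionModel = JTT,
    ):
        self.alignment = alignment
        self.substitution_model = substitution_model

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "SubfamilyModel":
        return cls(read_msa(path), **kwargs)

    def fit(
        self,
        bootstrap_replicates: int = 1000,
        seed: int = 0,
        z_threshold: float = 3.3,
        min_size: int = 5,
        min_species: int | None = None,
        support_min: float = 70.0,
        counts: str = "pairs",
        refine_replicates: bool = True,
    ) -> "SubfamilyResults":
        """Run the full delineation and return a results object."""
        aln = self.alignment
        species_of = {r.id: r.species for r in aln.records}
        D = distance_matrix(aln, self.substitution_model)
        tree = trees.bootstrap_supports(
            aln,
            self.substitution_model,
            trees.BootstrapConfig(bootstrap_replicates, seed),
            refine=refine_replicates,
        )
        initial = subfamilies.propose_initial_partition(
            tree, support_min, min_size, species_of, min_species
        )
        partition, audit_log = subfamilies.refine_partition(
            D, tree, initial, z_threshold, min_size, species_of,
            min_species, counts,
        )
        report = subfamilies.validate_partition(
            D, partition, z_threshold, min_size, species_of, min_species,
            counts,
        )
        return SubfamilyResults(
            model=self,
            distances=D,
            tree=tree,
            initial_partition=initial,
            partition=partition,
            report=report,
            audit_log=audit_log,
            params={
                "bootstrap_replicates": bootstrap_replicates,
                "seed": seed,
                "z_threshold": z_threshold,
                "min_size": min_size,
                "min_species": min_species,
                "support_min": support_min,
                "counts": counts,
            },
        )


@dataclass
class SubfamilyResults:
    """Fitted subfamily delineation: tree, partition and z audit."""

    model: SubfamilyModel
    distances: EvolutionaryDistanceMatrix
    tree: trees.PhylogeneticTree
    initial_partition: SubfamilyPartition
    partition: SubfamilyPartition
    report: ValidationReport
    audit_log: list[str]
    params: dict

    @property
    def n_subfamilies(self) -> int:
        return len(self.partition.groups)

    @property
    def z_values(self) -> pd.DataFrame:
        rows = [
            {
                "group_i": r.group_i,
                "group_j": r.group_j,
                "d_inter": r.d_inter,
                "d_intra_pooled": r.d_intra_pooled,
                "z": r.z,
                "degenerate": r.degenerate,
            }
            for r in self.report.records
        ]
        return pd.DataFrame(rows)

    def min_z(self) -> float:
        return self.report.min_z()

    def subfamily_tree(self, group: str, outgroup_from: str | None = None):
        """Rooted tree of one subfamily, outgroup-rooted per the protocol.

        The outgroup defaults to (up to three) sequences from the other
        subfamily with the highest z against ``group``.
        """
        part = self.partition
        if outgroup_from is None:
            zbest, outgroup_from = -np.inf, None
            for r in self.report.records:
                if group in (r.group_i, r.group_j) and r.z is not None:
                    other = r.group_j if r.group_i == group else r.group_i
                    if r.z > zbest:
                        zbest, outgroup_from = r.z, other
            if outgroup_from is None:
                raise subfamilies.PartitionError(
                    f"no partner subfamily to root {group!r}"
                )
        out_ids = set(sorted(part.groups[outgroup_from])[:3])
        keep = part.groups[group] | out_ids
        aln = self.model.alignment.subset_ids(keep)
        D = distance_matrix(aln, self.model.substitution_model)
        sub_tree = trees.build_tree(D)
        return trees.root_with_outgroup(sub_tree, out_ids)

    def summary(self) -> str:
        lines = [
            "Subfamily delineation results",
            "=============================",
            f"sequences: {len(self.model.alignment)}   "
            f"alignment columns: {self.model.alignment.length}",
            f"subfamilies: {self.n_subfamilies}   "
            f"non-grouped: {len(self.partition.non_grouped)}",
            f"validation: {'PASS' if self.report.passed else 'FAIL'}   "
            f"min z: {self.min_z():.3g}   "
            f"(threshold {self.params['z_threshold']})",
            "",
            "group    size  species",
        ]
        species_of = {
            r.id: r.species for r in self.model.alignment.records
        }
        for label in sorted(self.partition.groups):
            members = self.partition.groups[label]
            n_sp = subfamilies.count_species(members, species_of)
            lines.append(f"{label:<8} {len(members):>4}  {n_sp:>7}")
        if self.report.records:
            lines += ["", "pairwise z-values:"]
            for r in sorted(
                self.report.records, key=lambda r: (r.group_i, r.group_j)
            ):
                lines.append(
                    f"  z({r.group_i}, {r.group_j}) = {r.z:.3f}"
                    + ("  [degenerate]" if r.degenerate else "")
                )
        if self.audit_log:
            lines += ["", "refinement actions:"] + [
                f"  {a}" for a in self.audit_log
            ]
        return "\n".join(lines)


class SpecificityClassifier:
    """Substrate-specificity classes from in vivo fatty-acid profiles."""

    def __init__(self, profiles: list[specificity.SpecificityProfile]):
        self.profiles = profiles

    @classmethod
    def from_peak_tables(
        cls,
        peak_tables,
        control=None,
        standards: specificity.InternalStandardSet | None = None,
        response_factors: dict[str, float] | None = None,
    ) -> "SpecificityClassifier":
        """Build from raw peak tables via the quantitation pipeline."""
        clamp_log: list[str] = []
        profiles = specificity.profiles_from_peak_tables(
            peak_tables, control, standards, response_factors, clamp_log
        )
        obj = cls(profiles)
        obj.clamp_log = clamp_log
        return obj

    @classmethod
    def from_molpct_frame(cls, frame: pd.DataFrame) -> "SpecificityClassifier":
        """Build directly from a wide (enzyme x species) mol% table.

        Net concentrations are unknown in this path; the mol% vector is
        stored with its own sum (normally 100) as the total.
        """
        profiles = []
        for idx, row in frame.iterrows():
            molpct = {str(s): float(v) for s, v in row.items()}
            profiles.append(
                specificity.SpecificityProfile(
                    str(idx), dict(molpct), molpct, float(row.sum())
                )
            )
        return cls(profiles)

    def fit(
        self,
        k: int = 3,
        replicates: int = 1000,
        scales=clustering.DEFAULT_SCALES,
        seed: int = 0,
    ) -> "ClassificationResults":
        dend = clustering.multiscale_bootstrap(
            self.profiles, replicates, tuple(scales), seed, k
        )
        silhouettes = clustering.silhouette_diagnostics(self.profiles)
        return ClassificationResults(
            model=self,
            dendrogram=dend,
            k=k,
            silhouettes=silhouettes,
            params={"replicates": replicates, "seed": seed,
                    "scales": tuple(scales)},
        )


@dataclass
class ClassificationResults:
    """Fitted specificity classification: dendrogram, support, classes."""

    model: SpecificityClassifier
    dendrogram: clustering.ClassDendrogram
    k: int
    silhouettes: dict[int, float]
    params: dict

    @property
    def class_labels(self) -> dict[str, int]:
        return self.dendrogram.class_labels

    def classes(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for enzyme, label in sorted(self.class_labels.items()):
            out.setdefault(label, []).append(enzyme)
        return out

    def node_support(self) -> pd.DataFrame:
        d = self.dendrogram
        leafsets = d.node_leafsets()
        rows = []
        for t, leaves in enumerate(leafsets):
            nid = d.n + t
            rows.append(
                {
                    "node": nid,
                    "size": len(leaves),
                    "members": ";".join(sorted(leaves)),
                    "height": d.merges[t][2],
                    "au": d.au.get(nid, np.nan),
                    "bp": d.bp.get(nid, {}).get(1.0, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        d = self.dendrogram
        lines = [
            "Specificity classification results",
            "==================================",
            f"enzymes: {d.n}   classes (k): {self.k}   "
            f"bootstrap replicates: {self.params['replicates']} "
            f"x {len(self.params['scales'])} scales",
            "",
        ]
        for label, members in sorted(self.classes().items()):
            lines.append(f"class {label} ({len(members)} enzymes):")
            for m in members:
                lines.append(f"  {m}")
        lines += ["", "node support (AU / BP at scale 1):"]
        sup = self.node_support()
        for row in sup.itertuples(index=False):
            lines.append(
                f"  node {row.node} (n={row.size}): au={row.au:.3f} "
                f"bp={row.bp:.3f}"
            )
        if self.silhouettes:
            sil = ", ".join(
                f"k={k}: {v:.3f}" for k, v in sorted(self.silhouettes.items())
            )
            lines += ["", f"silhouette widths: {sil}"]
        return "\n".join(lines)
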