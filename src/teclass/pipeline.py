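"""End-to-end orchestration of the two analysis tracks.

``run_phylo`` goes from an MSA to a validated subfamily partition;
``run_specificity`` goes from peak tables to specificity classes.  Both
write their artifacts (TSV/JSON/Newick) plus a manifest capturing the
configuration hash, seeds and package version, sufficient to reproduce the
outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import TEClassError
from .models import SpecificityClassifier, SubfamilyModel
from .specificity import (
    InternalStandardSet,
    profiles_to_frame,
    read_concentration_table,
    read_peak_table,
)


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults mirror the published protocol
    (z > 3.3, >= 5 sequences from different species, 1000 bootstrap
    replicates on both tracks, k = 3 classes)."""

    msa: str | None = None
    peaks: str | None = None
    control: str | None = None
    z_threshold: float = 3.3
    min_size: int = 5
    min_species: int | None = None
    support_min: float = 70.0
    bootstrap_replicates: int = 1000
    clustering_replicates: int = 1000
    k: int = 3
    seed: int = 0
    counts: str = "pairs"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.min_size < 1:
            raise TEClassError("thresholds must be positive")
        if self.bootstrap_replicates < 1 or self.clustering_replicates < 1:
            raise TEClassError("replicates must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(config: PipelineConfig, outdir: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "config": dataclasses.asdict(config),
        "config_sha256_16": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_phylo(config: PipelineConfig, outdir: str | Path):
    """MSA -> distances -> tree -> bootstrap -> z-refined partition."""
    if not config.msa:
        raise TEClassError("config.msa is required for the phylogeny track")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = SubfamilyModel.from_fasta(config.msa)
    results = model.fit(
        bootstrap_replicates=config.bootstrap_replicates,
        seed=config.seed,
        z_threshold=config.z_threshold,
        min_size=config.min_size,
        min_species=config.min_species,
        support_min=config.support_min,
        counts=config.counts,
    )
    results.distances.to_tsv(outdir / "distances.tsv")
    results.tree.write(outdir / "tree.nwk")
    results.partition.to_tsv(outdir / "partition.tsv")
    payload = results.report.to_json()
    (outdir / "z_report.json").write_text(payload)
    (outdir / "audit_log.txt").write_text(
        "\n".join(results.audit_log) + ("\n" if results.audit_log else "")
    )
    (outdir / "summary.txt").write_text(results.summary() + "\n")
    _write_manifest(config, outdir, "phylo")
    if not results.report.passed:
        raise TEClassError(
            "final partition failed validation: "
            + "; ".join(results.report.violations)
        )
    return results


def run_specificity(config: PipelineConfig, outdir: str | Path):
    """Peak tables -> quantitation -> mol% -> Ward/AU classification."""
    if not config.peaks:
        raise TEClassError("config.peaks is required for the activity track")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak_tables = read_peak_table(config.peaks)
    control = None
    if config.control:
        try:
            control_tables = read_peak_table(config.control)
            control = next(iter(control_tables.values()))
        except TEClassError:
            control = next(
                iter(read_concentration_table(config.control).values())
            )
    classifier = SpecificityClassifier.from_peak_tables(
        peak_tables, control, InternalStandardSet()
    )
    results = classifier.fit(
        k=config.k,
        replicates=config.clustering_replicates,
        seed=config.seed,
    )
    profiles_to_frame(classifier.profiles).to_csv(
        outdir / "profiles.csv", index=False
    )
    results.node_support().to_csv(outdir / "node_support.csv", index=False)
    with open(outdir / "classes.tsv", "w") as fh:
        fh.write("enzyme\tclass\n")
        for enzyme, label in sorted(results.class_labels.items()):
            fh.write(f"{enzyme}\t{label}\n")
    (outdir / "dendrogram.nwk").write_text(results.dendrogram.newick() + "\n")
    (outdir / "diagnostics.json").write_text(
        json.dumps(
            {
                "silhouettes": results.silhouettes,
                "au": results.dendrogram.au,
                "bp_scale1": {
                    nid: by_scale.get(1.0)
                    for nid, by_scale in results.dendrogram.bp.items()
                },
            },
            indent=2,
        )
    )
    (outdir / "summary.txt").write_text(results.summary() + "\n")
    _write_manifest(config, outdir, "specificity")
    return results
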