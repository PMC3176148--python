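import json

import pandas as pd
import pytest
from click.testing import CliRunner

from teclass.alignio import write_msa
from teclass.cli import main as cli_main
from teclass.datasets import characterized_te_profiles
from teclass.errors import TEClassError
from teclass.models import SpecificityClassifier, SubfamilyModel
from teclass.pipeline import PipelineConfig, run_phylo, run_specificity
from teclass.synthetic import (
    ProfileSimSpec,
    SequenceSimSpec,
    simulate_profiles,
    simulate_subfamily_alignment,
)


@pytest.fixture(scope="module")
def small_case(tmp_path_factory):
    """Two-subfamily alignment and three-class peak tables on disk."""
    root = tmp_path_factory.mktemp("pipeline")
    spec = SequenceSimSpec(
        n_subfamilies=2, tips_per_subfamily=6, sites=200, seed=31
    )
    aln, truth, _ = simulate_subfamily_alignment(spec)
    msa = root / "aln.fa"
    write_msa(aln, msa)
    psim = simulate_profiles(ProfileSimSpec(profiles_per_class=4, seed=5))
    peaks = root / "peaks.csv"
    control = root / "control.csv"
    psim.peaks_frame().to_csv(peaks, index=False)
    psim.control_frame().to_csv(control, index=False)
    return {
        "root": root, "msa": msa, "truth": truth,
        "peaks": peaks, "control": control, "psim": psim,
    }


class TestSubfamilyModel:
    def test_fit_recovers_truth_and_summarizes(self, small_case):
        model = SubfamilyModel.from_fasta(small_case["msa"])
        res = model.fit(bootstrap_replicates=20, seed=2)
        truth = small_case["truth"]
        assert {frozenset(g) for g in res.partition.groups.values()} == {
            frozenset(g) for g in truth.groups.values()
        }
        assert res.report.passed and res.min_z() > 3.3
        text = res.summary()
        assert "subfamilies: 2" in text and "PASS" in text
        assert len(res.z_values) == 1

    def test_subfamily_tree_is_rooted_on_outgroup(self, small_case):
        model = SubfamilyModel.from_fasta(small_case["msa"])
        res = model.fit(bootstrap_replicates=10, seed=2)
        rooted = res.subfamily_tree(sorted(res.partition.groups)[0])
        assert rooted.root is not None


class TestSpecificityClassifier:
    def test_three_class_fit_from_peaks(self, small_case):
        psim = small_case["psim"]
        clf = SpecificityClassifier.from_peak_tables(
            psim.peak_tables,
            dict(ProfileSimSpec().control_background),
            psim.standards,
        )
        res = clf.fit(k=3, replicates=100, seed=1)
        classes = res.classes()
        assert len(classes) == 3
        # members of one true class share a predicted class
        for cls in ("I", "II", "III"):
            labels = {
                res.class_labels[e]
                for e, t in psim.true_labels.items() if t == cls
            }
            assert len(labels) == 1
        assert "classes (k): 3" in res.summary()

    def test_fit_from_molpct_frame(self):
        frame = characterized_te_profiles()
        res = SpecificityClassifier.from_molpct_frame(frame).fit(
            k=3, replicates=50, seed=0
        )
        assert set(res.class_labels) == set(frame.index)


class TestPipeline:
    def test_run_phylo_writes_reproducible_artifacts(self, small_case, tmp_path):
        config = PipelineConfig(
            msa=str(small_case["msa"]), bootstrap_replicates=10, seed=4
        )
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_phylo(config, out1)
        run_phylo(config, out2)
        for name in (
            "distances.tsv", "tree.nwk", "partition.tsv", "z_report.json",
            "summary.txt", "manifest.json",
        ):
            a, b = (out1 / name), (out2 / name)
            assert a.exists()
            assert a.read_bytes() == b.read_bytes()
        manifest = json.loads((out1 / "manifest.json").read_text())
        assert manifest["seed"] == 4

    def test_two_sequence_msa_fails_gracefully(self, tmp_path):
        msa = tmp_path / "two.fa"
        msa.write_text(">a|x\nMKVL\n>b|y\nMKVI\n")
        config = PipelineConfig(msa=str(msa), bootstrap_replicates=5)
        with pytest.raises(TEClassError):
            run_phylo(config, tmp_path / "out")

    def test_run_specificity_classes_match_truth(self, small_case, tmp_path):
        config = PipelineConfig(
            peaks=str(small_case["peaks"]),
            control=str(small_case["control"]),
            clustering_replicates=50,
            seed=6,
        )
        res = run_specificity(config, tmp_path / "spec")
        assert (tmp_path / "spec" / "classes.tsv").exists()
        assert (tmp_path / "spec" / "dendrogram.nwk").exists()
        truth = small_case["psim"].true_labels
        for cls in ("I", "II", "III"):
            labels = {
                res.class_labels[e] for e, t in truth.items() if t == cls
            }
            assert len(labels) == 1

    def test_k1_single_class(self, small_case, tmp_path):
        config = PipelineConfig(
            peaks=str(small_case["peaks"]),
            control=str(small_case["control"]),
            clustering_replicates=20,
            k=1,
        )
        res = run_specificity(config, tmp_path / "k1")
        assert set(res.class_labels.values()) == {1}

    def test_empty_peak_table_is_an_error(self, tmp_path):
        peaks = tmp_path / "empty.csv"
        peaks.write_text("enzyme,species,area\n")
        config = PipelineConfig(peaks=str(peaks))
        with pytest.raises(TEClassError):
            run_specificity(config, tmp_path / "out")


class TestCLI:
    def test_simulate_quantify_classify_chain(self, tmp_path):
        runner = CliRunner()
        simdir = tmp_path / "sim"
        r = runner.invoke(
            cli_main,
            ["simulate", "profiles", "--seed", "3", "--out", str(simdir)],
        )
        assert r.exit_code == 0, r.output
        profs = tmp_path / "profiles.csv"
        r = runner.invoke(
            cli_main,
            ["quantify", "--peaks", str(simdir / "peaks.csv"),
             "--control", str(simdir / "control.csv"),
             "--out", str(profs)],
        )
        assert r.exit_code == 0, r.output
        table = pd.read_csv(profs)
        assert {"enzyme", "species", "mol_pct"} <= set(table.columns)
        r = runner.invoke(
            cli_main,
            ["classify", "--profiles", str(profs), "-k", "3",
             "--replicates", "30", "--seed", "1",
             "--out", str(tmp_path / "cls")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "cls" / "classes.tsv").exists()

    def test_props_and_distances_commands(self, tmp_path, small_case):
        runner = CliRunner()
        fasta = tmp_path / "seqs.fa"
        fasta.write_text(
            ">pre|Cocos nucifera\nMAATSSLPDWSMLLK\n"
            ">mat|Cuphea viscosissima\nLPDWAAAKRHEWSQ-\n"
        )
        out = tmp_path / "props.tsv"
        r = runner.invoke(
            cli_main,
            ["props", "--fasta", str(fasta), "--cleave", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        table = pd.read_csv(out, sep="\t")
        assert list(table["id"]) == ["pre", "mat"]
        dist_out = tmp_path / "dist.tsv"
        r = runner.invoke(
            cli_main,
            ["distances", "--msa", str(small_case["msa"]),
             "--out", str(dist_out)],
        )
        assert r.exit_code == 0, r.output
        assert pd.read_csv(dist_out, sep="\t", index_col=0).shape == (12, 12)
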