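import json

import pytest
import yaml
from click.testing import CliRunner

from cbcdelim.cli import main as cli_main
from cbcdelim.errors import ConfigError
from cbcdelim.model import CbcDelimitation, TemplateRegion
from cbcdelim.pipeline import run_pipeline, simulate_command
from cbcdelim.refmodels import synthetic_its1_model
from cbcdelim.simulate import simulate_alignment, study_scale_config, write_simulation
from cbcdelim.io import Alignment, write_alignment


@pytest.fixture(scope="module")
def study_fit():
    cfg = study_scale_config(42)
    aln, tree, log = simulate_alignment(cfg)
    model = CbcDelimitation.from_simulation(aln, tree, log)
    return model.fit()


class TestModelResults:
    def test_summary_reports_clades_and_regions(self, study_fit):
        text = study_fit.summary()
        assert "CBC clades: 2" in text
        assert "ITS1" in text and "ITS2" in text
        assert "paraphyletic" in text

    def test_event_counts_table(self, study_fit):
        counts = study_fit.event_counts()
        assert counts.loc["ITS1", "hCBC"] == 3
        assert counts.loc["ITS2", "CBC"] == 1

    def test_save_writes_report_files(self, study_fit, tmp_path):
        paths = study_fit.save(tmp_path / "report")
        for name in ("events.tsv", "cbc_matrix.tsv", "clades.tsv",
                     "subclades.tsv", "deletions.tsv", "helices.tsv",
                     "edge_events.tsv", "report.json"):
            assert name in paths and paths[name].exists()
        report = json.loads(paths["report.json"].read_text())
        assert report["n_cbc_clades"] == 2 and report["n_subclades"] == 6

    def test_saved_reports_are_reproducible(self, tmp_path):
        cfg = study_scale_config(4)
        for sub in ("x", "y"):
            aln, tree, log = simulate_alignment(cfg)
            CbcDelimitation.from_simulation(aln, tree, log).fit() \
                .save(tmp_path / sub)
        for name in ("events.tsv", "cbc_matrix.tsv", "clades.tsv",
                     "subclades.tsv", "report.json"):
            assert (tmp_path / "x" / name).read_bytes() == \
                (tmp_path / "y" / name).read_bytes()


def _write_analysis_inputs(tmp_path, seed=13):
    """Simulate, dump files, and write a YAML config pointing at them."""
    aln, tree, log = simulate_command(None, tmp_path / "sim", preset_seed=seed)
    cfg = {
        "alignment": str(tmp_path / "sim" / "alignment.fasta"),
        "structures": [
            {"vienna": str(tmp_path / "sim" / "its1_template.vienna"),
             "region": "ITS1"},
            {"vienna": str(tmp_path / "sim" / "its2_template.vienna"),
             "region": "ITS2"},
        ],
        "tree": str(tmp_path / "sim" / "tree.nwk"),
        "template_id": log.template_taxon,
    }
    cfg_path = tmp_path / "analysis.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    return cfg_path, log


class TestPipeline:
    def test_file_round_trip_matches_direct_fit(self, tmp_path):
        """Template located by sequence search reproduces the exact maps."""
        cfg_path, log = _write_analysis_inputs(tmp_path)
        results = run_pipeline(cfg_path, tmp_path / "out")
        assert len(results.clades) == 2
        assert len(results.subclades) == 6
        assert (tmp_path / "out" / "report.json").exists()
        for region, pcm in results.maps.items():
            assert pcm.paired_cols == log.region_maps[region].paired_cols

    def test_missing_tree_still_emits_clades(self, tmp_path):
        cfg_path, _ = _write_analysis_inputs(tmp_path, seed=14)
        cfg = yaml.safe_load(cfg_path.read_text())
        del cfg["tree"]
        cfg_path.write_text(yaml.safe_dump(cfg))
        results = run_pipeline(cfg_path, tmp_path / "out2")
        assert len(results.clades) == 2
        assert not results.edge_maps and not results.monophyly

    def test_malformed_config_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("alignment: only_this\n")
        with pytest.raises(ConfigError):
            run_pipeline(p)


class TestTemplateAnchoring:
    def test_offset_located_by_sequence_search(self):
        rec, s = synthetic_its1_model()
        padded = "AUGC" + rec.residues + "GGAA"
        aln = Alignment([("tmpl", padded), ("o", padded)])
        model = CbcDelimitation(aln, [TemplateRegion(
            "ITS1", s, "tmpl", sequence=rec.residues)])
        pcm = model.project()["ITS1"]
        assert pcm.paired_cols[0] == (4 + s.to_dotbracket().index("(") + 1,) + \
            pcm.paired_cols[0][1:]
        assert pcm.unproject().pairs == s.pairs


class TestCli:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--preset-seed", "7",
                                     "--out", str(tmp_path / "sim")])
        assert r.exit_code == 0, r.output
        aln, tree, log = simulate_command(None, None, preset_seed=7)
        r2 = runner.invoke(cli_main, [
            "analyze",
            "--alignment", str(tmp_path / "sim" / "alignment.fasta"),
            "--structure", str(tmp_path / "sim" / "its1_template.vienna"),
            "--region", "ITS1",
            "--structure", str(tmp_path / "sim" / "its2_template.vienna"),
            "--region", "ITS2",
            "--tree", str(tmp_path / "sim" / "tree.nwk"),
            "--template-id", log.template_taxon,
            "--out", str(tmp_path / "out"),
        ])
        assert r2.exit_code == 0, r2.output
        assert "CBC clades: 2" in r2.output

    def test_patterns_command(self, tmp_path):
        aln = Alignment([("a", "ACGU"), ("b", "ACGG")])
        write_alignment(aln, tmp_path / "a.fasta")
        r = CliRunner().invoke(cli_main, ["patterns", "--alignment",
                                          str(tmp_path / "a.fasta")])
        assert r.exit_code == 0 and r.output.strip() == "4"

    def test_fold_command_prints_dotbracket(self, tmp_path):
        aln = Alignment([("a", "GGGAAACCC"), ("b", "GGGAAACCC")])
        write_alignment(aln, tmp_path / "a.fasta")
        r = CliRunner().invoke(cli_main, ["fold", "--alignment",
                                          str(tmp_path / "a.fasta")])
        assert r.exit_code == 0 and r.output.strip() == "(((...)))"

    def test_malformed_config_exits_nonzero(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("alignment: nothing\n")
        r = CliRunner().invoke(cli_main, ["analyze", "--config", str(p),
                                          "--out", str(tmp_path / "o")])
        assert r.exit_code != 0
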