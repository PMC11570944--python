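"""Synthetic fixtures, file formats, scenario bundles, and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from hdxsim.cli import main as cli_main
from hdxsim.io import (
    load_workflow_config,
    read_fasta,
    read_peptide_table,
    read_protection_table,
    sequence_from_arg,
    workflow_to_config,
    write_fasta,
)
from hdxsim.peptides import PeptideRegion, percent_back_exchange
from hdxsim.scenarios import (
    SCENARIO_NAMES,
    ScenarioSpec,
    named_scenario,
    quench_bx_workflow,
    run_scenario,
    standard_bottom_up_workflow,
)
from hdxsim.synthetic import SyntheticSpec, generate_synthetic


class TestSynthetic:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        spec = SyntheticSpec(seed=1, length_range=(50, 50))
        a = generate_synthetic(spec, tmp_path / "a")
        b = generate_synthetic(spec, tmp_path / "b")
        assert a.sequence == b.sequence
        assert np.array_equal(a.protection.log_p, b.protection.log_p)
        assert [(p.start, p.end) for p in a.peptides] == [
            (p.start, p.end) for p in b.peptides
        ]
        for name in ("synthetic.fasta", "protection.csv", "peptides.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_composition_weights_make_homopolymers(self):
        bundle = generate_synthetic(
            SyntheticSpec(seed=3, composition={"A": 1.0}, length_range=(30, 30))
        )
        assert bundle.sequence == "A" * 30

    def test_every_generated_peptide_has_an_observable_site(self):
        peptides = []
        for seed in range(10):
            bundle = generate_synthetic(SyntheticSpec(seed=seed))
            peptides.extend(bundle.peptides)
        assert len(peptides) >= 100
        for pep in peptides:
            assert pep.N >= 3
            assert pep.capacity >= 1

    def test_protection_values_respect_block_bounds(self):
        spec = SyntheticSpec(seed=5, flexible_log_p=(0.0, 1.0), rigid_log_p=(4.0, 7.0))
        bundle = generate_synthetic(spec)
        log_p = bundle.protection.log_p
        assert np.all((log_p <= 1.0) | ((log_p >= 4.0) & (log_p <= 7.0)))

    def test_infeasible_tiling_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_synthetic(
                SyntheticSpec(seed=0, length_range=(5, 5), peptide_length_range=(9, 12))
            )


class TestFasta:
    def test_wrapped_and_unwrapped_records_agree(self, tmp_path):
        seq = "ACDEFGHIKLMNQRSTVWY" * 7
        write_fasta([("wide", seq)], tmp_path / "wide.fasta", width=10_000)
        write_fasta([("wrapped", seq)], tmp_path / "wrapped.fasta", width=60)
        assert read_fasta(tmp_path / "wide.fasta")[0][1] == seq
        assert read_fasta(tmp_path / "wrapped.fasta")[0][1] == seq

    def test_round_trip_of_generated_fixture(self, tmp_path):
        bundle = generate_synthetic(SyntheticSpec(seed=11), tmp_path)
        records = read_fasta(tmp_path / "synthetic.fasta")
        assert records[0][1] == bundle.sequence

    def test_invalid_residue_reported_with_position_and_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">rec1\nACDEFG\nHIXKLM\n")
        with pytest.raises(ValueError, match=r"bad\.fasta:3.*position 9"):
            read_fasta(path)

    def test_non_fasta_input_rejected(self, tmp_path):
        path = tmp_path / "notfasta.txt"
        path.write_text("ACDEFGHI\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(path)

    def test_sequence_from_arg_accepts_inline_and_path(self, tmp_path):
        assert sequence_from_arg("acdefghi") == "ACDEFGHI"
        write_fasta([("x", "ACDEFGHI")], tmp_path / "x.fasta")
        assert sequence_from_arg(str(tmp_path / "x.fasta")) == "ACDEFGHI"


class TestTables:
    def test_protection_and_peptide_tables_round_trip(self, tmp_path):
        bundle = generate_synthetic(SyntheticSpec(seed=2), tmp_path)
        profile = read_protection_table(
            tmp_path / "protection.csv", length=len(bundle.sequence)
        )
        assert np.allclose(profile.log_p, bundle.protection.log_p)
        peptides = read_peptide_table(tmp_path / "peptides.csv", bundle.sequence)
        assert [(p.start, p.end) for p in peptides] == [
            (p.start, p.end) for p in bundle.peptides
        ]


class TestWorkflowConfig:
    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_config_round_trip(self, tmp_path, fmt):
        workflow = standard_bottom_up_workflow()
        config = workflow_to_config(workflow)
        path = tmp_path / f"wf.{fmt}"
        if fmt == "yaml":
            path.write_text(yaml.safe_dump(config))
        else:
            path.write_text(json.dumps(config))
        loaded = load_workflow_config(path)
        assert loaded == workflow

    def test_packaged_configs_match_named_workflows(self):
        from hdxsim.scenarios import example_config_path

        loaded = load_workflow_config(example_config_path("standard_bottom_up"))
        assert loaded == standard_bottom_up_workflow()
        loaded = load_workflow_config(example_config_path("quench_bx_200s"))
        assert loaded == quench_bx_workflow(200.0)
        with pytest.raises(KeyError):
            example_config_path("missing")

    def test_invalid_config_raises_before_computation(self, tmp_path):
        path = tmp_path / "wf.yaml"
        path.write_text(yaml.safe_dump({"stages": [{"label": "x"}]}))
        with pytest.raises(ValueError, match="invalid workflow config"):
            load_workflow_config(path)


class TestScenarios:
    def test_named_scenarios_resolve(self):
        assert set(SCENARIO_NAMES) == {
            "standard-bottom-up",
            "shortened-bottom-up",
            "quench-bx-200s",
            "quench-bx-1000s",
            "quench-bx-2000s",
        }
        with pytest.raises(KeyError, match="unknown scenario"):
            named_scenario("nope")

    def test_run_scenario_bundle_is_deterministic(self, tmp_path):
        spec = named_scenario("quench-bx-1000s")
        r1 = run_scenario(spec, tmp_path / "r1")
        r2 = run_scenario(spec, tmp_path / "r2")
        for key in ("trajectory", "uptake", "assessment"):
            assert r1.paths[key].read_bytes() == r2.paths[key].read_bytes()
        summary = json.loads(r1.paths["assessment"].read_text())
        assert summary["percent_bx_control"] == pytest.approx(r1.percent_bx)
        assert "rate table checksum" in r1.paths["log"].read_text()

    def test_empty_time_grid_is_config_error(self, tmp_path):
        spec = ScenarioSpec("empty", workflow=quench_bx_workflow(200.0), t_hdx_s=())
        with pytest.raises(ValueError, match="empty"):
            run_scenario(spec, tmp_path)


class TestCli:
    def test_rates_command_writes_expected_columns(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "rates.csv"
        result = runner.invoke(
            cli_main,
            ["rates", "--seq", "ACDEFGHI", "--acidity", "7.4", "--scale", "pD",
             "--temp-k", "295", "--direction", "HtoD", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        header = out.read_text().splitlines()[0]
        assert header == "position,residue,k_ch_per_s,exchanging"

    def test_bx_command_matches_library(self, tmp_path):
        config = tmp_path / "wf.yaml"
        workflow = standard_bottom_up_workflow()
        config.write_text(yaml.safe_dump(workflow_to_config(workflow)))
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["bx", "--seq", "ACDEFGHI", "--config", str(config)]
        )
        assert result.exit_code == 0, result.output
        expected = percent_back_exchange(
            workflow, PeptideRegion("p", 1, 8, "ACDEFGHI")
        )
        assert float(result.output.strip()) == pytest.approx(expected, abs=0.01)

    def test_scenario_and_synth_commands(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["scenario", "quench-bx-200s", "--out-dir", str(tmp_path / "sc")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "sc" / "assessment.json").exists()
        result = runner.invoke(
            cli_main, ["synth", "--seed", "4", "--out-dir", str(tmp_path / "syn")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "syn" / "peptides.csv").exists()
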