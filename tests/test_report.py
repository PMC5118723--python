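import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from polyploid_eld import cli, destats, report, simdata, tables_io
from polyploid_eld._util import pct_half_up
from polyploid_eld.errors import DomainError, PipelineError
from polyploid_eld.report import PipelineConfig, call_expressed, run_pipeline, tf_family_summary
from polyploid_eld.tables_io import ExpressionTable


def _table(rows: dict, lib: int = 10**6) -> ExpressionTable:
    df = pd.DataFrame(rows, dtype=np.int64).T
    df.columns = ["A", "B", "C"]
    df.index.name = "feature_id"
    return ExpressionTable(df, library_sizes=pd.Series({"A": lib, "B": lib, "C": lib}))


class TestRounding:
    def test_half_up_on_exact_ties(self):
        # exact tie cases must go up, not to even
        assert pct_half_up(125, 1000) == 12.50
        assert pct_half_up(1, 800) == 0.13  # 0.125% rounds up
        assert pct_half_up(3166, 9209) == 34.38
        assert pct_half_up(4467, 9209) == 48.51

    def test_zero_denominator(self):
        assert pct_half_up(5, 0) == 0.0


class TestExpressed:
    def test_hand_fixture_venn_regions(self):
        table = _table(
            {
                "g1": [5, 5, 5],   # ABC
                "g2": [5, 0, 0],   # A only
                "g3": [0, 5, 0],   # B only
                "g4": [0, 0, 5],   # C only
                "g5": [5, 5, 0],   # AB
                "g6": [0, 5, 5],   # BC
            }
        )
        sets, regions = call_expressed(table)
        assert regions == {
            "A_only": 1, "B_only": 1, "C_only": 1,
            "AB": 1, "AC": 0, "BC": 1, "ABC": 1,
        }
        assert sets["A"] == {"g1", "g2", "g5"}

    def test_identical_columns_all_triple(self):
        table = _table({"g1": [3, 3, 3], "g2": [9, 9, 9]})
        _, regions = call_expressed(table)
        assert regions["ABC"] == 2
        assert sum(regions.values()) == 2

    def test_zero_threshold_means_any_read(self):
        table = _table({"g1": [1, 0, 0]})
        sets, _ = call_expressed(table, min_norm=0.0)
        assert sets["A"] == {"g1"} and sets["B"] == set()

    def test_negative_threshold_rejected(self, tiny_table):
        with pytest.raises(DomainError):
            call_expressed(tiny_table, min_norm=-1.0)


class TestTFSummary:
    def test_hand_computed_family_means(self):
        tf = pd.DataFrame(
            {
                "feature_id": ["g1", "g2", "g3", "g4", "g5"],
                "term_id": ["bHLH", "bHLH", "MYB", "MYB", "MYB"],
                "term_name": "", "namespace": "",
            }
        )
        norm = pd.DataFrame(
            {
                "A": [10.0, 30.0, 10.0, 0.0, 5.0],
                "B": [10.0, 30.0, 10.0, 0.0, 5.0],
                "C": [10.0, 30.0, 10.0, 0.0, 5.0],
            },
            index=["g1", "g2", "g3", "g4", "g5"],
        )
        res = tf_family_summary({"g1", "g2", "g3", "g4", "g5"}, tf, norm)
        by_family = res.set_index("family")
        # bHLH: (10+30)/2 = 20; MYB: g4 unexpressed -> (10+5)/2 = 7.5
        assert by_family.loc["bHLH", "mean_expression"] == pytest.approx(20.0)
        assert by_family.loc["MYB", "mean_expression"] == pytest.approx(7.5)
        assert by_family.loc["MYB", "expressed_count"] == 2
        assert res.iloc[0]["family"] == "bHLH"  # sorted by mean expression

    def test_single_gene_family(self):
        tf = pd.DataFrame(
            {"feature_id": ["g1"], "term_id": ["WRKY"], "term_name": "", "namespace": ""}
        )
        norm = pd.DataFrame({"A": [10.0], "B": [10.0], "C": [10.0]}, index=["g1"])
        res = tf_family_summary({"g1"}, tf, norm)
        assert res.iloc[0]["mean_expression"] == pytest.approx(10.0)


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    """One full pipeline execution on a small synthetic experiment."""
    tmp = tmp_path_factory.mktemp("pipeline")
    cfg_sim = simdata.SimulationConfig(
        n_genes=600, n_mirnas=60, library_sizes=(10**6,) * 3, seed=23
    )
    exp = simdata.simulate_counts(cfg_sim)
    paths = simdata.write_experiment(exp, tmp / "sim")

    # minimal annotation + slim + TF tables over the simulated genes
    genes = list(exp.gene_counts.feature_ids)
    ann = pd.DataFrame(
        {
            "feature_id": genes[:200],
            "term_id": ["GO:1"] * 100 + ["GO:2"] * 100,
            "term_name": "", "namespace": "",
        }
    )
    tables_io.write_annotation(ann, tmp / "ann.tsv")
    pd.DataFrame(
        {"term_id": ["GO:1", "GO:2"], "namespace": ["BP", "MF"],
         "slim_term": ["metabolic process", "binding"]}
    ).to_csv(tmp / "slim.tsv", sep="\t", index=False)
    tf = pd.DataFrame(
        {"feature_id": genes[:40], "term_id": ["bHLH"] * 20 + ["MYB"] * 20,
         "term_name": "", "namespace": ""}
    )
    tables_io.write_annotation(tf, tmp / "tf.tsv")

    cfg = PipelineConfig(
        gene_counts=paths["gene_counts"],
        mirna_counts=paths["mirna_counts"],
        gene_library_sizes=paths["library_sizes"],
        mirna_library_sizes=paths["library_sizes"],
        target_pairs=paths["target_pairs"],
        annotation=str(tmp / "ann.tsv"),
        slim_map=str(tmp / "slim.tsv"),
        tf_table=str(tmp / "tf.tsv"),
        outdir=str(tmp / "out"),
    )
    return cfg, run_pipeline(cfg), exp, tmp


class TestPipeline:
    def test_report_totals_internally_consistent(self, pipeline_run):
        _, rep, _, _ = pipeline_run
        de = rep["stages"]["de_genes"]
        for comp, tallies in de["per_comparison"].items():
            assert tallies["total_de"] == tallies["up"] + tallies["down"]
        pat = rep["stages"]["patterns"]
        assert pat["eld_total"] == pat["eld_a_total"] + pat["eld_b_total"]
        assert pat["eld_a_total"] == (
            pat["counts"]["ELD_a_up"] + pat["counts"]["ELD_a_down"]
        )
        nonadd = rep["stages"]["nonadditive"]
        assert nonadd["total"] == nonadd["up"] + nonadd["down"]

    def test_percentages_recomputable_from_report(self, pipeline_run):
        _, rep, _, _ = pipeline_run
        de = rep["stages"]["de_genes"]
        assert de["deg_share_of_detected"] == pct_half_up(
            de["deg_total_vs_parents"], de["detected_total"]
        )
        pat = rep["stages"]["patterns"]
        assert pat["eld_a_share_of_degs"] == pct_half_up(
            pat["eld_a_total"], pat["deg_total"]
        )

    def test_network_gene_total_is_union_cardinality(self, pipeline_run):
        cfg, rep, _, _ = pipeline_run
        net = rep["stages"]["network"]
        edges = pd.read_csv(f"{cfg.outdir}/related_edges.tsv", sep="\t")
        assert net["edge_total"] == len(edges)
        assert net["related_gene_total"] == edges["gene_id"].nunique()

    def test_rerun_is_deterministic(self, pipeline_run):
        cfg, rep, _, tmp = pipeline_run
        import dataclasses

        cfg2 = dataclasses.replace(cfg, outdir=str(tmp / "out2"))
        rep2 = run_pipeline(cfg2)
        assert json.dumps(rep, sort_keys=True) == json.dumps(rep2, sort_keys=True)

    def test_missing_input_aborts_with_stage_name(self, pipeline_run, tmp_path):
        cfg, _, _, _ = pipeline_run
        import dataclasses

        bad = dataclasses.replace(
            cfg, gene_counts=str(tmp_path / "nope.tsv"), outdir=str(tmp_path / "o")
        )
        with pytest.raises(PipelineError, match="read_counts"):
            run_pipeline(bad)


class TestCLI:
    def test_simulate_then_de_roundtrip(self, tmp_path):
        runner = CliRunner()
        outdir = tmp_path / "sim"
        res = runner.invoke(
            cli.main,
            ["simulate", "--n-genes", "200", "--n-mirnas", "20",
             "--library-size", "1000000", "--seed", "4",
             "--outdir", str(outdir)],
        )
        assert res.exit_code == 0, res.output
        de_out = tmp_path / "de.tsv"
        res = runner.invoke(
            cli.main,
            ["de", "--counts", str(outdir / "gene_counts.tsv"),
             "--comparison", "C-vs-A", "--out", str(de_out)],
        )
        assert res.exit_code == 0, res.output
        tallies = json.loads(res.output.strip().splitlines()[-1])
        assert tallies["up"] + tallies["down"] + tallies["ns"] == 200

    def test_report_command(self, pipeline_run, tmp_path):
        cfg, _, _, _ = pipeline_run
        import dataclasses

        cfg2 = dataclasses.replace(cfg, outdir=str(tmp_path / "cli_out"))
        cfg_path = tmp_path / "config.json"
        payload = dataclasses.asdict(cfg2)
        for key in ("mrna_thresholds", "mirna_thresholds", "pattern_thresholds"):
            payload.pop(key)
        cfg_path.write_text(json.dumps(payload))
        runner = CliRunner()
        res = runner.invoke(cli.main, ["report", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "cli_out" / "report.json").exists()
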