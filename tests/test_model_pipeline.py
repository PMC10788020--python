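"""End-to-end analysis through the model object, pipeline and CLI."""

import json
import math
import time

import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from cubtk.cds_io import write_fasta
from cubtk.cli import main as cli_main
from cubtk.model import CodonUsageAnalysis
from cubtk.pipeline import RunConfig, run_all
from cubtk.synthetic_cds import SyntheticSpec, generate_geneset


@pytest.fixture(scope="module")
def geneset28():
    genes, _ = generate_geneset(
        SyntheticSpec(n_genes=28, bias_mode="dirichlet", concentration=0.8, seed=21)
    )
    return genes


@pytest.fixture(scope="module")
def fitted(geneset28):
    return CodonUsageAnalysis(geneset28).fit()


def test_full_pipeline_fast_and_complete(geneset28):
    start = time.perf_counter()
    results = CodonUsageAnalysis(geneset28).fit()
    assert time.perf_counter() - start < 10.0
    summary = results.summary_dict()
    for key in (
        "n_genes", "total_codons", "pooled_gcall", "pooled_enc",
        "n_high_frequency_codons", "n_optimal_codons",
        "n_enc_ratio_positive", "n_enc_ratio_within_0.05",
        "neutrality_slope", "neutrality_r",
    ):
        assert key in summary
    frame = results.metrics_frame
    assert len(frame) == 28
    assert not frame.drop(columns=["gene"]).isna().any().any()


def test_summary_matches_module_outputs(fitted):
    s = fitted.summary_dict()
    assert s["n_genes"] == len(fitted.gene_metrics)
    assert s["total_codons"] == fitted.pooled_counts.total
    assert s["n_optimal_codons"] == int(fitted.optimal_report["optimal"].sum())
    assert s["n_high_frequency_codons"] == len(fitted.high_frequency)
    assert s["n_enc_ratio_positive"] == int((fitted.enc_plot["enc_ratio"] > 0).sum())
    assert s["neutrality_slope"] == pytest.approx(fitted.neutrality.slope, abs=5e-5)
    assert "Codon usage bias" in fitted.summary()


def test_gene_metrics_ranges(fitted):
    frame = fitted.metrics_frame
    for col in ("gc1", "gc2", "gc3", "gcall", "gc3s"):
        assert frame[col].between(0, 100).all()
    assert frame["enc"].between(20, 61).all()
    assert frame["cai"].between(0, 1).all()
    assert frame["fop"].between(0, 1).all()
    assert frame["cbi"].between(-1, 1).all()
    assert (frame["codon_counts"] == [len(g.codons) for g in fitted.model.genes]).all()


def test_results_bundle_written(fitted, tmp_path):
    written = fitted.to_dir(tmp_path)
    for name in ("gene_metrics.tsv", "pooled_metrics.tsv", "rscu_pooled.tsv",
                 "optimal_codons.tsv", "encplot.tsv", "neutrality.tsv",
                 "pr2.tsv", "correlations_r.tsv", "summary.json"):
        assert name in written and (tmp_path / name).exists()
    rscu_table = pd.read_csv(tmp_path / "rscu_pooled.tsv", sep="\t")
    assert len(rscu_table) == 61
    assert rscu_table["count"].sum() == fitted.pooled_counts.total


def test_run_all_deterministic_reruns(geneset28, tmp_path):
    fasta = tmp_path / "genes.fasta"
    write_fasta(geneset28, fasta)
    outputs = []
    for run in ("r1", "r2"):
        config = RunConfig(input=str(fasta), out_dir=str(tmp_path / run))
        summary = run_all(config)
        assert summary["n_genes"] == 28
        outputs.append((tmp_path / run / "gene_metrics.tsv").read_bytes())
        manifest = (tmp_path / run / "MANIFEST").read_text().split()
        assert manifest == ["extract_filter", "metrics_diagnostics_selection", "summary"]
        assert json.loads((tmp_path / run / "summary.json").read_text())["n_genes"] == 28
    assert outputs[0] == outputs[1]


def test_run_all_with_species_manifest(tmp_path):
    manifest_rows = []
    for i in range(3):
        genes, _ = generate_geneset(SyntheticSpec(n_genes=8, seed=60 + i))
        path = tmp_path / f"sp{i}.fasta"
        write_fasta(genes, path)
        manifest_rows.append(f"species_{i}\t{path}")
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text("\n".join(manifest_rows) + "\n")
    config = RunConfig(manifest=str(manifest), out_dir=str(tmp_path / "out"))
    summary = run_all(config)
    assert summary["n_species"] == 3
    newick = (tmp_path / "out" / "dendrogram.nwk").read_text()
    assert newick.count("species_") == 3


def test_run_config_validation(tmp_path):
    with pytest.raises(ValueError, match="input file or a species manifest"):
        RunConfig()
    with pytest.raises(ValueError, match="positive"):
        RunConfig(input="x.fasta", min_length_bp=0)
    cfg = RunConfig(input="x.fasta")
    assert cfg.digest() == RunConfig(input="x.fasta").digest()
    assert cfg.digest() != RunConfig(input="y.fasta").digest()


def test_cli_simulate_then_metrics(tmp_path):
    runner = CliRunner()
    sim_dir = tmp_path / "sim"
    result = runner.invoke(
        cli_main, ["simulate", "--seed", "5", "--out-dir", str(sim_dir)]
    )
    assert result.exit_code == 0, result.output
    assert (sim_dir / "synthetic_cds.fasta").exists()
    assert (sim_dir / "truth.json").exists()

    out_dir = tmp_path / "metrics"
    result = runner.invoke(
        cli_main,
        ["metrics", "--cds", str(sim_dir / "synthetic_cds.fasta"),
         "--out-dir", str(out_dir)],
    )
    assert result.exit_code == 0, result.output
    assert "Codon usage bias" in result.output
    assert (out_dir / "gene_metrics.tsv").exists()


def test_cli_run_with_yaml_config(tmp_path):
    genes, _ = generate_geneset(SyntheticSpec(n_genes=12, seed=33))
    fasta = tmp_path / "in.fasta"
    write_fasta(genes, fasta)
    cfg_path = tmp_path / "cubtk.yaml"
    cfg_path.write_text(yaml.safe_dump(
        {"input": str(fasta), "out_dir": str(tmp_path / "out")}
    ))
    runner = CliRunner()
    result = runner.invoke(cli_main, ["run", "--config", str(cfg_path)])
    assert result.exit_code == 0, result.output
    assert json.loads((tmp_path / "out" / "summary.json").read_text())["n_genes"] == 12
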