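"""One-command orchestration: raw CDS in, full report bundle out.

``run_all`` composes the whole analysis — CDS filtering, per-gene and
pooled metrics, diagnostics, optimal codons, and (when a species manifest
is given) the comparative RSCU dendrogram — writing TSV/JSON outputs and a
MANIFEST of completed stages. Any stage failure is re-raised with the
stage name; outputs of completed stages are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import comparative_clustering as cc
from .cds_io import filter_cds, read_cds, write_fasta
from .model import CodonUsageAnalysis

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("cubtk")


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    input: str | None = None
    format: str = "fasta"
    manifest: str | None = None  # TSV: species <tab> path, for clustering
    out_dir: str = "cubtk_out"
    min_length_bp: int = 300
    bias_fraction: float = 0.10
    delta_threshold: float = 0.08
    linkage: str = "average"
    enc_curve: str = "corrected"
    cai_reference: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0 or self.bias_fraction <= 0 or self.delta_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.input is None and self.manifest is None:
            raise ValueError("config needs an input file or a species manifest")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str, manifest: list[str], outdir: Path):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                manifest.append(name)
            (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_all(config: RunConfig) -> dict:
    """Run the configured analysis end to end; returns the summary dict."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("cubtk %s, config %s", __version__, config.digest())
    completed: list[str] = []
    summary: dict = {"config_digest": config.digest(), "version": __version__}

    results = None
    if config.input is not None:
        with _stage("extract_filter", completed, outdir):
            candidates = read_cds(config.input, config.format)
            genes, report = filter_cds(candidates, min_length_bp=config.min_length_bp)
            write_fasta(genes, outdir / "filtered_cds.fasta")

        with _stage("metrics_diagnostics_selection", completed, outdir):
            cai_ref = None
            if config.cai_reference:
                ref_raw = read_cds(config.cai_reference, "fasta")
                cai_ref, _ = filter_cds(ref_raw, min_length_bp=config.min_length_bp)
            model = CodonUsageAnalysis(
                genes,
                bias_fraction=config.bias_fraction,
                delta_threshold=config.delta_threshold,
                cai_reference=cai_ref,
                enc_curve=config.enc_curve,
                filter_report=report,
            )
            results = model.fit()
            results.to_dir(outdir)
            summary.update(results.summary_dict())

    if config.manifest is not None:
        with _stage("comparative_clustering", completed, outdir):
            manifest_df = pd.read_csv(
                config.manifest, sep="\t", names=["species", "path"], header=None
            )
            species_cds = {}
            for row in manifest_df.itertuples(index=False):
                sp_genes, _ = filter_cds(
                    read_cds(row.path, "fasta"), min_length_bp=config.min_length_bp
                )
                species_cds[row.species] = sp_genes
            matrix = cc.rscu_matrix(species_cds)
            clustering = cc.cluster(matrix, linkage=config.linkage)
            matrix.to_csv(outdir / "rscu_matrix.tsv", sep="\t")
            (outdir / "dendrogram.nwk").write_text(clustering.to_newick() + "\n")
            summary["n_species"] = len(matrix)

    with _stage("summary", completed, outdir):
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
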