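"""Top-level analysis interface: :class:`CodonUsageAnalysis` /
:class:`CodonUsageResults`.

The model object holds a validated gene set and the analysis settings; its
``fit()`` runs the full pipeline — per-gene composition indices and ENC,
pooled RSCU and high-frequency codons, ENC-extreme bias groups, CAI/CBI/
Fop against the derived reference and optimal sets, ENC-plot, neutrality
regression, PR2 coordinates and the parameter correlation matrix — and
returns a results object carrying every table plus a printable summary.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import bias_diagnostics as diag
from . import codon_metrics as cm
from . import codon_selection as sel
from ._report import round_half_up
from .cds_io import CodingSequence, FilterReport, filter_cds, read_cds
from .genetic_code import GeneticCode, aa_three_letter, dna_to_rna, rna_to_dna, standard_code

__all__ = ["CodonUsageAnalysis", "CodonUsageResults"]


class CodonUsageAnalysis:
    """Codon-usage-bias analysis of a validated CDS set.

    Parameters
    ----------
    genes : sequence of CodingSequence
        Validated genes (use :meth:`from_fasta` / :meth:`from_genbank` to
        apply the CDS filters on raw input).
    bias_fraction : float
        Fraction of genes in each ENC-extreme group (default 0.10).
    delta_threshold : float
        dRSCU cutoff of the optimal-codon rule (default 0.08).
    cai_reference : sequence of CodingSequence, optional
        Reference gene set for CAI weights; defaults to the pooled
        high-bias (lowest-ENC) group of the input itself.
    enc_curve : {"corrected", "as-printed"}
        Expected-ENC curve variant for the ENC-plot.
    """

    def __init__(
        self,
        genes: Sequence[CodingSequence],
        *,
        code: GeneticCode | None = None,
        bias_fraction: float = 0.10,
        delta_threshold: float = 0.08,
        cai_reference: Sequence[CodingSequence] | None = None,
        enc_curve: str = "corrected",
        filter_report: FilterReport | None = None,
    ) -> None:
        if not genes:
            raise ValueError("empty gene set")
        self.genes = list(genes)
        self.code = code or standard_code()
        self.bias_fraction = bias_fraction
        self.delta_threshold = delta_threshold
        self.cai_reference = list(cai_reference) if cai_reference else None
        self.enc_curve = enc_curve
        self.filter_report = filter_report

    @classmethod
    def from_fasta(cls, path, min_length_bp: int = 300, **kwargs) -> "CodonUsageAnalysis":
        genes, report = filter_cds(read_cds(path, "fasta"), min_length_bp=min_length_bp)
        return cls(genes, filter_report=report, **kwargs)

    @classmethod
    def from_genbank(cls, path, min_length_bp: int = 300, **kwargs) -> "CodonUsageAnalysis":
        genes, report = filter_cds(read_cds(path, "genbank"), min_length_bp=min_length_bp)
        return cls(genes, filter_report=report, **kwargs)

    def fit(self) -> "CodonUsageResults":
        code = self.code
        gene_counts = {g.gene_id: cm.count_codons(g) for g in self.genes}
        pooled = cm.pool_counts(gene_counts.values(), scope="pooled")
        metrics = [cm.compute_composition_metrics(g, code) for g in self.genes]

        pooled_rscu = cm.rscu(pooled, code)
        hi_freq = sel.high_frequency_codons(pooled_rscu, code)

        groups = None
        optimal_report = None
        try:
            groups = sel.build_bias_groups(metrics, gene_counts, self.bias_fraction)
            optimal_report = sel.optimal_codons(
                groups, pooled_rscu, self.delta_threshold, code
            )
            optimal_set = frozenset(
                rna_to_dna(c)
                for c in optimal_report.loc[optimal_report["optimal"], "codon"]
            )
        except ValueError as exc:
            warnings.warn(f"bias-group construction failed ({exc}); "
                          "using high-frequency codons as the optimal set")
            optimal_set = hi_freq

        if self.cai_reference is not None:
            ref_counts = cm.pool_counts(
                [cm.count_codons(g) for g in self.cai_reference], scope="cai_reference"
            )
        elif groups is not None:
            ref_counts = groups.high_counts
        else:
            ref_counts = pooled
        weights = cm.reference_weights(ref_counts, code)

        for m in metrics:
            counts = gene_counts[m.gene_id]
            m.cai = cm.cai(counts, weights, code)
            if optimal_set:
                m.fop = cm.fop(counts, optimal_set, code)
                m.cbi = cm.cbi(counts, optimal_set, code)

        metrics_frame = cm.metrics_to_frame(metrics)
        enc_plot = diag.enc_plot_table(metrics, variant=self.enc_curve)
        neutrality = diag.neutrality_fit(metrics) if len(metrics) >= 3 else None
        pr2 = diag.pr2_table([gene_counts[m.gene_id] for m in metrics], code)
        correlations = (
            diag.parameter_correlations(metrics_frame) if len(metrics) >= 3 else None
        )

        gc1, gc2, gc3, gcall = cm.positional_gc(pooled)
        a3s, t3s, c3s, g3s, gc3s = cm.silent_site_composition(pooled, code)
        pooled_row = pd.Series(
            {
                "codon_counts": pooled.total,
                "t3s": t3s,
                "c3s": c3s,
                "a3s": a3s,
                "g3s": g3s,
                "gc1": gc1,
                "gc2": gc2,
                "gc3": gc3,
                "gcall": gcall,
                "gc3s": gc3s,
                "enc": cm.enc(pooled, code),
            }
        )

        return CodonUsageResults(
            model=self,
            gene_counts=gene_counts,
            pooled_counts=pooled,
            gene_metrics=metrics,
            metrics_frame=metrics_frame,
            pooled_metrics=pooled_row,
            pooled_rscu=pooled_rscu,
            high_frequency=frozenset(hi_freq),
            bias_groups=groups,
            optimal_report=optimal_report,
            optimal_set=frozenset(optimal_set),
            cai_weights=weights,
            enc_plot=enc_plot,
            neutrality=neutrality,
            pr2=pr2,
            correlations=correlations,
        )


@dataclass
class CodonUsageResults:
    """Fitted codon-usage analysis: every table the pipeline produces."""

    model: CodonUsageAnalysis
    gene_counts: dict[str, cm.CodonCounts]
    pooled_counts: cm.CodonCounts
    gene_metrics: list[cm.GeneMetrics]
    metrics_frame: pd.DataFrame
    pooled_metrics: pd.Series
    pooled_rscu: cm.RSCUProfile
    high_frequency: frozenset[str]
    bias_groups: sel.BiasGroups | None
    optimal_report: pd.DataFrame | None
    optimal_set: frozenset[str]
    cai_weights: dict[str, float]
    enc_plot: pd.DataFrame
    neutrality: diag.NeutralityResult | None
    pr2: pd.DataFrame
    correlations: diag.CorrelationMatrix | None

    @property
    def n_genes(self) -> int:
        return len(self.gene_metrics)

    def rscu_frame(self) -> pd.DataFrame:
        """Pooled per-codon counts and RSCU over the 61 sense codons."""
        code = self.model.code
        rows = []
        for c in code.sense_codons:
            aa = code.codon_to_aa[c]
            rows.append(
                {
                    "amino_acid": aa_three_letter(aa),
                    "codon": dna_to_rna(c),
                    "count": self.pooled_counts.get(c),
                    "rscu": self.pooled_rscu.values.get(c, math.nan),
                }
            )
        return pd.DataFrame(rows).sort_values(
            ["amino_acid", "codon"], ignore_index=True
        )

    def summary_dict(self) -> dict:
        ratios = self.enc_plot["enc_ratio"]
        out = {
            "n_genes": self.n_genes,
            "total_codons": int(self.pooled_counts.total),
            "pooled_gc1": round_half_up(self.pooled_metrics["gc1"]),
            "pooled_gc2": round_half_up(self.pooled_metrics["gc2"]),
            "pooled_gc3": round_half_up(self.pooled_metrics["gc3"]),
            "pooled_gcall": round_half_up(self.pooled_metrics["gcall"]),
            "pooled_gc3s": round_half_up(self.pooled_metrics["gc3s"]),
            "pooled_enc": round_half_up(self.pooled_metrics["enc"]),
            "mean_enc": round_half_up(self.metrics_frame["enc"].mean()),
            "n_high_frequency_codons": len(self.high_frequency),
            "n_optimal_codons": len(self.optimal_set),
            "n_enc_ratio_positive": int((ratios > 0).sum()),
            "n_enc_ratio_within_0.05": int(ratios.between(-0.05, 0.05).sum()),
        }
        if self.neutrality is not None:
            out["neutrality_slope"] = round_half_up(self.neutrality.slope, 4)
            out["neutrality_r"] = round_half_up(self.neutrality.pearson_r, 4)
            out["neutrality_p"] = float(self.neutrality.p_value)
        return out

    def summary(self) -> str:
        """Human-readable analysis summary."""
        s = self.summary_dict()
        lines = [
            "Codon usage bias analysis",
            "=" * 54,
            f"Genes analysed:            {s['n_genes']}",
            f"Total sense codons:        {s['total_codons']}",
            f"Pooled GC1/GC2/GC3 (%):    {s['pooled_gc1']} / {s['pooled_gc2']} / {s['pooled_gc3']}",
            f"Pooled GCall / GC3s (%):   {s['pooled_gcall']} / {s['pooled_gc3s']}",
            f"Pooled ENC (mean ENC):     {s['pooled_enc']} ({s['mean_enc']})",
            f"High-frequency codons:     {s['n_high_frequency_codons']} (pooled RSCU > 1)",
            f"Optimal codons:            {s['n_optimal_codons']} "
            f"(group RSCU > 1, dRSCU > {self.model.delta_threshold})",
            f"ENC ratio > 0:             {s['n_enc_ratio_positive']} of {s['n_genes']} genes",
            f"ENC ratio in [-0.05,0.05]: {s['n_enc_ratio_within_0.05']} of {s['n_genes']} genes",
        ]
        if self.neutrality is not None:
            lines.append(
                f"Neutrality GC12~GC3:       slope {s['neutrality_slope']}, "
                f"r {s['neutrality_r']}, p {s['neutrality_p']:.4g}"
            )
        return "\n".join(lines)

    def _rounded_metrics(self) -> pd.DataFrame:
        df = self.metrics_frame.copy()
        for col in df.columns:
            if col == "gene":
                continue
            nd = 2
            df[col] = df[col].map(lambda v: round_half_up(v, nd))
        return df

    def to_dir(self, outdir: str | Path) -> list[str]:
        """Write the full report bundle as TSV/JSON; returns filenames written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[str] = []

        def _write(df: pd.DataFrame, name: str) -> None:
            df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6g")
            written.append(name)

        if self.model.filter_report is not None:
            _write(self.model.filter_report.to_dataframe(), "filter_report.tsv")
        _write(self._rounded_metrics(), "gene_metrics.tsv")
        pooled = self.pooled_metrics.map(round_half_up).to_frame().T
        pooled["codon_counts"] = int(self.pooled_counts.total)
        _write(pooled, "pooled_metrics.tsv")
        _write(self.rscu_frame(), "rscu_pooled.tsv")
        if self.optimal_report is not None:
            _write(self.optimal_report, "optimal_codons.tsv")
        _write(self.enc_plot, "encplot.tsv")
        if self.neutrality is not None:
            _write(
                self.neutrality.to_frame(self.metrics_frame["gene"]), "neutrality.tsv"
            )
        _write(self.pr2, "pr2.tsv")
        if self.correlations is not None:
            self.correlations.r.to_csv(outdir / "correlations_r.tsv", sep="\t")
            self.correlations.p.to_csv(outdir / "correlations_p.tsv", sep="\t")
            self.correlations.stars().to_csv(outdir / "correlations_stars.tsv", sep="\t")
            written += ["correlations_r.tsv", "correlations_p.tsv", "correlations_stars.tsv"]
        (outdir / "summary.json").write_text(json.dumps(self.summary_dict(), indent=2))
        written.append("summary.json")
        return written
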