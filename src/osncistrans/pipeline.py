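"""End-to-end cis/trans analysis of OR repertoires.

The question: are strain differences in OSN-subtype proportions driven in
cis or in trans?  Under cis regulation, parental fold changes between B6
and CAST should be reproduced between the B6 and CAST alleles inside an
F1 hybrid; under trans regulation the F1 alleles equalize.  The pipeline
normalizes parental and F1 samples jointly (depth, then OSN content),
filters to genes with adequate SNP-informative counts, estimates allelic
ratios, deconvolves total F1 expression into allele-specific values,
computes parental and allelic log2 fold changes, calibrates technical
noise with in-silico F1 replicates, and summarizes concordance with Lin's
ccc and its bias-correction factor C_b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allelic import allelic_ratio, deconvolve_alleles, informative_gene_filter
from .calibration import build_insilico_f1, compute_deviation, correct_allelic_fc
from .containers import AllelicCountTable, CountMatrix, SizeFactors
from .errors import InvalidArgumentError, OsnCisTransError
from .io import (read_allelic_table, read_count_matrix, read_json, write_json,
                 write_table)
from .normalization import (apply_depth_normalization, apply_osn_normalization,
                            depth_size_factors, marker_gate, osn_size_factors)
from .stats import least_squares_slope, lin_ccc, log2_fold_change

log = logging.getLogger(__name__)


@dataclass
class CisTransOptions:
    """Tunable choices of the cis/trans analysis.

    ``pseudocount`` is added to doubly-normalized values before log2 fold
    changes; ``n_insilico_rounds`` in-silico F1 replicate sets (with
    rotated parental pairings) are averaged into the per-gene deviation;
    ``apply_osn_to_allelic`` controls whether OSN-content factors are also
    applied to SNP-informative counts (depth factors always are).
    """

    marker_threshold: float = 0.7
    marker_method: str = "spearman"
    pseudocount: float = 1.0
    pooling: str = "pooled"
    apply_osn_to_allelic: bool = True
    n_insilico_rounds: int = 32
    pairing: list | None = None
    fc_orientation: str = "cast_vs_b6"
    seed: int = 0


@dataclass
class CisTransReport:
    """Machine-readable result of the cis/trans analysis."""

    ccc_raw: float
    ccc_corrected: float
    c_b_raw: float
    c_b_corrected: float
    pearson_raw: float
    pearson_corrected: float
    slope_raw: float
    slope_corrected: float
    genes_total: int
    genes_informative: int
    table: pd.DataFrame = field(repr=False)
    provenance: dict = field(default_factory=dict, repr=False)

    def summary_dict(self) -> dict:
        return {
            "ccc_raw": self.ccc_raw,
            "ccc_corrected": self.ccc_corrected,
            "c_b_raw": self.c_b_raw,
            "c_b_corrected": self.c_b_corrected,
            "pearson_raw": self.pearson_raw,
            "pearson_corrected": self.pearson_corrected,
            "slope_raw": self.slope_raw,
            "slope_corrected": self.slope_corrected,
            "genes_total": self.genes_total,
            "genes_informative": self.genes_informative,
            "provenance": self.provenance,
        }


def _strain_means(normalized: CountMatrix, samples) -> pd.Series:
    return normalized.counts.loc[:, list(samples)].mean(axis=1)


def _stage(name):
    """Decorate pipeline stage errors with the stage name."""
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, OsnCisTransError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False
    return _ctx()


def _allelic_fc(
    total_normalized: CountMatrix,
    allelic: AllelicCountTable,
    f1_samples,
    depth_f: SizeFactors,
    osn_f: SizeFactors,
    genes,
    opts: CisTransOptions,
) -> tuple[pd.Series, pd.DataFrame]:
    """Allele-2 vs allele-1 (CAST vs B6) log2 fold change from one allelic table."""
    weights = 1.0 / depth_f.reindex(f1_samples).values
    if opts.apply_osn_to_allelic:
        weights = weights * osn_f.reindex(f1_samples).values
    sub = AllelicCountTable(
        allelic.table[allelic.table["gene"].isin(set(genes))].copy(),
        allele_labels=allelic.allele_labels)
    ratios, _ = allelic_ratio(sub, pooling="pooled", sample_weights=weights)
    f1_means = _strain_means(total_normalized, f1_samples)
    decon = deconvolve_alleles(f1_means, ratios)
    fc = pd.Series(
        log2_fold_change(decon["allele2_value"].to_numpy(),
                         decon["allele1_value"].to_numpy(),
                         pseudocount=opts.pseudocount),
        index=decon["gene"].to_numpy())
    return fc, decon


def cistrans_analysis(
    b6: CountMatrix,
    cast: CountMatrix,
    f1_total: CountMatrix,
    f1_allelic: AllelicCountTable,
    options: CisTransOptions | None = None,
) -> CisTransReport:
    """Run the full cis/trans concordance analysis on in-memory objects.

    Fold changes are oriented CAST vs B6 (allele 2 vs allele 1).  Returns
    a report whose per-gene table carries parental and allelic (raw and
    corrected) log2 fold changes over the informative gene set.
    """
    opts = options or CisTransOptions()
    if not (b6.genes.equals(cast.genes) and b6.genes.equals(f1_total.genes)):
        raise InvalidArgumentError("parental and F1 matrices must share one gene index")

    with _stage("depth_normalization"):
        combined_counts = pd.concat([b6.counts, cast.counts, f1_total.counts], axis=1)
        combined = CountMatrix(combined_counts, b6.gene_class.copy())
        depth_f = depth_size_factors(combined)
        depth_normed = apply_depth_normalization(combined, depth_f)

    with _stage("osn_normalization"):
        gate = marker_gate(depth_normed, threshold=opts.marker_threshold,
                           method=opts.marker_method)
        osn_f = osn_size_factors(depth_normed, gate.kept)
        normalized = apply_osn_normalization(depth_normed, osn_f)

    with _stage("informative_filter"):
        filt = informative_gene_filter(
            f1_allelic, depth_f,
            osn_f if opts.apply_osn_to_allelic else None)
        kept = filt.kept

    with _stage("parental_fold_changes"):
        b6_mean = _strain_means(normalized, b6.samples).loc[kept]
        cast_mean = _strain_means(normalized, cast.samples).loc[kept]
        parental_fc = pd.Series(
            log2_fold_change(cast_mean.to_numpy(), b6_mean.to_numpy(),
                             pseudocount=opts.pseudocount),
            index=pd.Index(kept, name="gene"))

    with _stage("allelic_fold_changes"):
        allelic_fc_raw, decon = _allelic_fc(
            normalized, f1_allelic, f1_total.samples, depth_f, osn_f, kept, opts)

    with _stage("insilico_calibration"):
        pi_hat = f1_allelic.informative_fraction(f1_total)
        f1_depths = f1_total.counts.sum(axis=0).to_numpy(dtype=float)
        rounds = []
        b6_ids = list(b6.samples)
        cast_ids = list(cast.samples)
        k = min(len(b6_ids), len(cast_ids))
        for r in range(opts.n_insilico_rounds):
            if opts.pairing is not None:
                pairing = opts.pairing
            else:
                pairing = [(b6_ids[j], cast_ids[(j + r) % k]) for j in range(k)]
            parental_ids = b6_ids + cast_ids
            content_w = (osn_f.reindex(parental_ids).values
                         / depth_f.reindex(parental_ids).values)
            ins_total, ins_allelic = build_insilico_f1(
                b6, cast, f1_depths, pairing=pairing,
                seed=opts.seed * 1009 + r, informative_fraction=pi_hat,
                content_weights=content_w)
            ins_combined = CountMatrix(
                pd.concat([b6.counts, cast.counts, ins_total.counts], axis=1),
                b6.gene_class.copy())
            s_r = depth_size_factors(ins_combined)
            dn_r = apply_depth_normalization(ins_combined, s_r)
            gate_r = marker_gate(dn_r, threshold=opts.marker_threshold,
                                 method=opts.marker_method)
            f_r = osn_size_factors(dn_r, gate_r.kept)
            norm_r = apply_osn_normalization(dn_r, f_r)
            fc_r, _ = _allelic_fc(norm_r, ins_allelic, ins_total.samples,
                                  s_r, f_r, kept, opts)
            rounds.append(fc_r)
        deviation = compute_deviation(rounds, parental_fc)

    with _stage("correction"):
        corrected = correct_allelic_fc(allelic_fc_raw, deviation)

    with _stage("concordance"):
        table = corrected.merge(
            parental_fc.rename("parental_log2fc"), left_on="gene", right_index=True)
        table = table.merge(
            filt.totals.rename("informative_normalized_total"),
            left_on="gene", right_index=True, how="left")
        finite = np.isfinite(table["parental_log2fc"]) & \
            np.isfinite(table["allelic_log2fc_raw"])
        sub = table[finite]
        raw = lin_ccc(sub["allelic_log2fc_raw"], sub["parental_log2fc"])
        cor = lin_ccc(sub["allelic_log2fc_corrected"], sub["parental_log2fc"])
        slope_raw = least_squares_slope(sub["parental_log2fc"],
                                        sub["allelic_log2fc_raw"])
        slope_cor = least_squares_slope(sub["parental_log2fc"],
                                        sub["allelic_log2fc_corrected"])

    provenance = {
        "package_version": __version__,
        "options": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(opts).items()},
        "markers_kept": sorted(gate.kept),
        "marker_correlations": {k: round(v, 6) for k, v in gate.correlations.items()},
        "informative_quartile": filt.quartile,
        "n_samples": {"B6": int(b6.samples.size), "CAST": int(cast.samples.size),
                      "F1": int(f1_total.samples.size)},
        "genes_at_stage": {
            "input": int(b6.or_genes.size),
            "with_informative_counts": int(filt.n_total),
            "after_quartile_filter": len(kept),
            "in_concordance": int(sub.shape[0]),
        },
    }
    return CisTransReport(
        ccc_raw=raw.ccc, ccc_corrected=cor.ccc,
        c_b_raw=raw.c_b, c_b_corrected=cor.c_b,
        pearson_raw=raw.pearson_r, pearson_corrected=cor.pearson_r,
        slope_raw=slope_raw, slope_corrected=slope_cor,
        genes_total=int(b6.or_genes.size), genes_informative=len(kept),
        table=table, provenance=provenance)


@dataclass
class PipelineConfig:
    """File-level configuration of a cis/trans run (paths + options)."""

    b6_counts: str
    cast_counts: str
    f1_counts: str
    f1_allelic: str
    gene_classes: str | None = None
    sample_meta: str | None = None
    outdir: str = "cistrans_out"
    options: CisTransOptions = field(default_factory=CisTransOptions)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = read_json(path)
        opts = CisTransOptions(**raw.pop("options", {}))
        return cls(**raw, options=opts)


def run_cistrans(config: PipelineConfig) -> CisTransReport:
    """File-based entry point: read inputs, analyze, write report + tables."""
    kw = dict(gene_class_path=config.gene_classes,
              sample_meta_path=config.sample_meta)
    b6 = read_count_matrix(config.b6_counts, **kw)
    cast = read_count_matrix(config.cast_counts, **kw)
    f1_total = read_count_matrix(config.f1_counts, **kw)
    f1_allelic = read_allelic_table(config.f1_allelic)
    report = cistrans_analysis(b6, cast, f1_total, f1_allelic, config.options)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(report.summary_dict(), outdir / "cistrans_report.json")
    write_table(report.table, outdir / "cistrans_genes.tsv")
    return report
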