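"""End-to-end synthetic-study pipeline.

Chains every stage — simulate, call peaks, consensus, annotate, shuffle
enrichment, summit redefinition, counting, NB differential accessibility,
expression integration, motif enrichment and the TF network — and writes
deterministic plain-text outputs.  Primarily a convenience for the CLI and
for reproducing the whole analysis in one call; each stage remains usable
on its own through the library API.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .annotate import (
    annotate_peaks,
    call_peaks_simple,
    feature_distribution,
    relative_enrichment,
    width_stats,
)
from .diffaccess import (
    consensus_peaks,
    count_cut_sites,
    nb_wald_test,
    redefine_peaks,
    sample_correlation,
)
from .integrate import (
    compute_fpkm,
    differential_expression,
    quadrant_classify,
    quintile_groups,
    tss_profile,
    ora_enrichment,
)
from .intervals import IntervalSet
from .motifs import motif_enrichment, pfm_to_pwm, scan_sequences, tf_network, write_network
from .synth import SynthConfig, default_pfms, simulate_study, write_study

__all__ = ["PipelineResult", "run_pipeline", "extract_sequences"]

_PROMOTER_CLASSES = ["Promoter (<=1kb)", "Promoter (1-2kb)", "Promoter (2-3kb)"]


def extract_sequences(sequences: dict, intervals: IntervalSet) -> dict:
    """Interval name -> genomic subsequence (forward strand)."""
    out = {}
    for r in intervals.df.itertuples(index=False):
        out[r.name] = sequences[r.chrom][r.start : r.end]
    return out


@dataclass
class PipelineResult:
    """Everything the end-to-end run computed, stage by stage."""

    study: object
    sample_peaks: dict
    consensus: dict
    annotated: pd.DataFrame
    distribution: pd.Series
    enrichment: pd.DataFrame
    widths: object
    redefined: object
    counts: object
    atac: pd.DataFrame
    correlation: pd.DataFrame
    rna: pd.DataFrame
    fpkm: pd.DataFrame
    quintiles: pd.Series
    profiles: pd.DataFrame
    quadrants: pd.DataFrame
    motif_table: pd.DataFrame
    network: object
    ora: pd.DataFrame


def _toy_gene_sets(gene_ids, de_genes, rng) -> dict:
    """Deterministic toy gene sets for the ORA stage.

    One set collects the planted DE genes (so over-representation is
    recoverable), the rest are random draws from the gene universe.
    """
    sets = {"planted_deg": sorted(de_genes)}
    ids = np.asarray(sorted(gene_ids), dtype=object)
    for k in range(5):
        size = int(rng.integers(10, 40))
        sets[f"random_set_{k}"] = sorted(rng.choice(ids, size=size, replace=False))
    return sets


def run_pipeline(
    cfg: SynthConfig | None = None,
    outdir=None,
    n_shuffles: int = 1000,
    min_samples: int = 2,
    count_mode: str = "cutsites",
) -> PipelineResult:
    """Run the full synthetic analysis; optionally write outputs to ``outdir``.

    Deterministic for a fixed ``cfg.seed``: running twice with the same
    configuration produces byte-identical output files.
    """
    cfg = cfg or SynthConfig()
    cfg.validate()
    study = simulate_study(cfg)
    sizes = study.annotation.chrom_sizes
    frags = study.fragments_by_sample()
    sample_groups = study.sample_groups

    sample_peaks = {
        s: call_peaks_simple(f, sizes, sample=s) for s, f in frags.items()
    }
    consensus = consensus_peaks(sample_peaks, sample_groups, min_samples=min_samples)

    # annotation arm on the cross-group union of consensus peaks
    union_frames = [c.intervals.df[["chrom", "start", "end"]] for _, c in sorted(consensus.items())]
    from .intervals import merge as _merge

    union = _merge(IntervalSet(pd.concat(union_frames, ignore_index=True), sizes))
    udf = union.df.copy()
    udf["name"] = [f"union_{i:05d}" for i in range(len(udf))]
    union = IntervalSet(udf, sizes)
    annotated = annotate_peaks(union, study.annotation)
    distribution = feature_distribution(annotated)
    enrichment = relative_enrichment(
        union,
        study.annotation,
        sizes,
        n_shuffles=n_shuffles,
        seed=np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000])),
    )
    widths = width_stats(annotated)

    # differential accessibility arm
    redefined = redefine_peaks(consensus, frags, sizes)
    counts = count_cut_sites(frags, redefined, sample_groups, mode=count_mode)
    test_g = cfg.elevated_group
    ref_g = next(g for g in cfg.groups if g != test_g)
    atac = nb_wald_test(counts, (test_g, ref_g))
    correlation = sample_correlation(counts.counts)

    # expression arm
    rna_groups = {c: c.rsplit("_", 1)[0] for c in study.gene_counts.columns}
    rna = differential_expression(
        study.gene_counts, study.gene_lengths, rna_groups, (test_g, ref_g)
    )
    fpkm = compute_fpkm(study.gene_counts, study.gene_lengths)
    quintiles = quintile_groups(fpkm.mean(axis=1))
    profiles, _ = tss_profile(frags, study.annotation, gene_groups=quintiles)

    ann_re = annotate_peaks(redefined, study.annotation)
    prom = ann_re[ann_re["feature_class"].isin(_PROMOTER_CLASSES)]
    promoter_atac = pd.DataFrame(
        {
            "gene_id": prom["gene_id"].to_numpy(),
            "peak_id": prom["name"].to_numpy(),
            "log2FC": atac.loc[prom["name"], "log2FC"].to_numpy(),
            "q": atac.loc[prom["name"], "q"].to_numpy(),
            "abs_distance": prom["tss_distance"].abs().to_numpy(),
        }
    )
    quadrants = quadrant_classify(promoter_atac, rna)

    dual = quadrants.loc[quadrants["quadrant"] != "", "gene_id"]
    universe = study.annotation.genes["gene_id"]
    ora_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2000]))
    gene_sets = _toy_gene_sets(universe, study.truth.de_genes, ora_rng)
    if len(dual):
        ora = ora_enrichment(dual, gene_sets, universe)
    else:
        ora = pd.DataFrame(columns=["set", "k", "K", "n", "N", "p", "q"])

    # motif arm: opened differential OCRs vs non-differential OCRs
    up_names = atac.index[atac["call"] == "up"]
    ns_names = atac.index[atac["call"] == "ns"]
    rdf = redefined.intervals.df.set_index("name")

    def _subset(names):
        sub = rdf.loc[list(names)].rename_axis("name").reset_index()
        return IntervalSet(sub)

    fg = extract_sequences(study.sequences, _subset(up_names))
    bg = extract_sequences(study.sequences, _subset(ns_names))
    pfms = default_pfms()
    if fg and bg:
        motif_table = motif_enrichment(pfms, fg, bg)
        diff_names = atac.index[atac["call"] != "ns"]
        diff_seqs = extract_sequences(study.sequences, _subset(diff_names))
        tf_targets = {
            p.matrix_id: set(scan_sequences(pfm_to_pwm(p), diff_seqs)["seq_id"])
            for p in pfms
        }
        try:
            network = tf_network(tf_targets, rna, motif_table, min_jaccard=0.0001)
        except ValueError:
            network = None
    else:
        motif_table = pd.DataFrame()
        network = None

    result = PipelineResult(
        study, sample_peaks, consensus, annotated, distribution, enrichment,
        widths, redefined, counts, atac, correlation, rna, fpkm, quintiles,
        profiles, quadrants, motif_table, network, ora,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_study(res.study, outdir / "synth")
    ff = "%.6g"
    for s in sorted(res.sample_peaks):
        _io.write_narrowpeak(res.sample_peaks[s], outdir / f"peaks_{s}.narrowPeak")
    for g in sorted(res.consensus):
        _io.write_bed(res.consensus[g].intervals, outdir / f"consensus_{g}.bed")
    res.annotated.to_csv(outdir / "annotated_peaks.tsv", sep="\t", index=False, float_format=ff)
    res.distribution.rename("percent").to_csv(outdir / "feature_distribution.tsv", sep="\t", float_format=ff)
    res.enrichment.to_csv(outdir / "relative_enrichment.tsv", sep="\t", float_format=ff)
    res.widths.per_class.to_csv(outdir / "width_stats.tsv", sep="\t", index=False, float_format=ff)
    _io.write_narrowpeak(res.redefined, outdir / "redefined_peaks.narrowPeak")
    res.counts.counts.to_csv(outdir / "cut_site_counts.tsv", sep="\t")
    res.atac.to_csv(outdir / "atac_differential.tsv", sep="\t", float_format=ff)
    res.correlation.to_csv(outdir / "sample_correlation.tsv", sep="\t", float_format=ff)
    res.rna.to_csv(outdir / "rna_differential.tsv", sep="\t", float_format=ff)
    res.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t", float_format=ff)
    res.quintiles.to_csv(outdir / "quintiles.tsv", sep="\t")
    res.profiles.to_csv(outdir / "tss_profiles.tsv", sep="\t", float_format=ff)
    res.quadrants.to_csv(outdir / "quadrants.tsv", sep="\t", index=False, float_format=ff)
    pd.Series(res.quadrants.attrs["counts"]).rename("n_genes").to_csv(
        outdir / "quadrant_counts.tsv", sep="\t"
    )
    res.ora.to_csv(outdir / "ora.tsv", sep="\t", index=False, float_format=ff)
    if len(res.motif_table):
        res.motif_table.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False, float_format=ff)
    if res.network is not None:
        write_network(res.network, outdir / "tf_network_edges.tsv",
                      outdir / "tf_network.graphml")
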