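"""Coupling chromatin openness to gene expression.

FPKM computation, expression quintile groups, TSS/gene-body metagene
profiles of cut-site density, joint quadrant classification of promoter
accessibility and expression changes, and generic hypergeometric gene-set
over-representation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeAnnotation
from .diffaccess import CountMatrix, nb_wald_test, pooled_cut_positions

__all__ = [
    "compute_fpkm",
    "differential_expression",
    "quintile_groups",
    "QUINTILE_LABELS",
    "tss_profile",
    "quadrant_classify",
    "QUADRANT_LABELS",
    "ora_enrichment",
]

QUINTILE_LABELS = ["lower", "low", "mid", "high", "higher"]
QUADRANT_LABELS = [
    "open_up_expr_up",
    "open_up_expr_down",
    "open_down_expr_up",
    "open_down_expr_down",
]

RNA_LFC_THRESHOLD = 1.0
RNA_Q_THRESHOLD = 0.05


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    mapped_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon model per million mapped fragments.

    ``FPKM = count * 1e9 / (length_bp * mapped_total)``; by default the
    mapped total is the sample's column sum.  Scaling counts and totals by a
    common factor leaves FPKM unchanged.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    if mapped_totals is None:
        mapped_totals = counts.sum(axis=0)
    mapped_totals = mapped_totals.reindex(counts.columns)
    if (mapped_totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    return counts * 1e9 / np.outer(lengths.to_numpy(), mapped_totals.to_numpy())


def differential_expression(
    counts: pd.DataFrame,
    lengths: pd.Series,
    sample_groups: dict,
    contrast: tuple = ("CY", "Y"),
    lfc_threshold: float = RNA_LFC_THRESHOLD,
    q_threshold: float = RNA_Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene NB Wald differential expression plus group-mean FPKM.

    Same test as the accessibility arm, at the expression thresholds
    (|log2FC| >= 1, q <= 0.05 by default).  Adds ``fpkm_<group>`` columns
    and ``mean_fpkm`` to the differential table.
    """
    cm = CountMatrix(counts, sample_groups, feature_lengths=lengths)
    res = nb_wald_test(cm, contrast, lfc_threshold=lfc_threshold, q_threshold=q_threshold)
    fpkm = compute_fpkm(counts, lengths)
    for g in sorted(set(sample_groups.values())):
        cols = [s for s in counts.columns if sample_groups[s] == g]
        res[f"fpkm_{g}"] = fpkm[cols].mean(axis=1)
    res["mean_fpkm"] = fpkm.mean(axis=1)
    return res


def quintile_groups(mean_fpkm: pd.Series) -> pd.Series:
    """Assign genes to five expression groups by FPKM quintile thresholds.

    Thresholds are the 20/40/60/80th percentiles (linear interpolation);
    a gene whose FPKM ties a threshold goes to the lower group, and
    zero-FPKM genes stay in "lower".  With all-equal FPKM every gene lands
    in "lower" (degenerate; a warning is emitted).
    """
    if len(mean_fpkm) < 5:
        raise ValueError("need >= 5 genes for quintile grouping")
    x = mean_fpkm.to_numpy(dtype=float)
    thresholds = np.percentile(x, [20, 40, 60, 80])
    idx = np.searchsorted(thresholds, x, side="left")
    if np.all(x == x[0]):
        warnings.warn("all FPKM values equal; every gene assigned to 'lower'")
    labels = np.array(QUINTILE_LABELS, dtype=object)[idx]
    return pd.Series(labels, index=mean_fpkm.index, name="quintile")


def tss_profile(
    fragments_by_sample: dict,
    annotation: GenomeAnnotation,
    gene_groups: pd.Series | None = None,
    flank: int = 3000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> tuple:
    """Metagene cut-site density over gene bodies and +/-``flank`` bp.

    Each gene contributes a vector of cut-site density (cuts per bp,
    normalized to cuts per million): fixed ``flank_bin``-bp bins over the
    upstream flank, the body length-scaled to ``body_bins`` bins, fixed bins
    downstream.  Minus-strand genes are reversed so the left edge is always
    upstream.  ``gene_groups`` (gene_id -> label) averages genes per group;
    without it a single "all" group is returned.  Genes with a body shorter
    than ``body_bins`` bp are skipped and counted.

    Returns ``(profiles, n_skipped)`` where profiles is a DataFrame with one
    row per group and ``2*flank/flank_bin + body_bins`` columns.
    """
    cuts = pooled_cut_positions(fragments_by_sample)
    total_cuts = sum(len(v) for v in cuts.values())
    if total_cuts == 0:
        raise ValueError("no cut sites in the supplied fragments")
    n_flank_bins = flank // flank_bin
    n_bins = 2 * n_flank_bins + body_bins

    genes = annotation.genes
    if gene_groups is None:
        gene_groups = pd.Series("all", index=genes["gene_id"])

    sums: dict = {}
    counts_per_group: dict = {}
    skipped = 0
    for r in genes.itertuples(index=False):
        if r.gene_id not in gene_groups.index:
            continue
        body_len = r.end - r.start
        if body_len < body_bins:
            skipped += 1
            continue
        up_edges = r.start - flank + flank_bin * np.arange(n_flank_bins + 1)
        body_edges = r.start + np.round(
            np.arange(body_bins + 1) * body_len / body_bins
        ).astype(np.int64)
        down_edges = r.end + flank_bin * np.arange(n_flank_bins + 1)
        edges = np.concatenate([up_edges, body_edges[1:], down_edges[1:]])
        ch = cuts.get(r.chrom, np.empty(0, np.int64))
        pos = np.searchsorted(ch, np.clip(edges, 0, None), side="left")
        binned = np.diff(pos).astype(float)
        widths = np.diff(edges).astype(float)
        density = np.divide(binned, widths, out=np.zeros_like(binned), where=widths > 0)
        if r.strand == "-":
            density = density[::-1]
        label = gene_groups.loc[r.gene_id]
        if label not in sums:
            sums[label] = np.zeros(n_bins)
            counts_per_group[label] = 0
        sums[label] += density
        counts_per_group[label] += 1

    scale = 1e6 / total_cuts
    profiles = pd.DataFrame(
        {g: scale * sums[g] / max(counts_per_group[g], 1) for g in sorted(sums)}
    ).T
    profiles.index.name = "group"
    return profiles, skipped


def quadrant_classify(
    promoter_atac: pd.DataFrame,
    rna: pd.DataFrame,
    atac_lfc: float = 0.58,
    rna_lfc: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Joint classification of promoter accessibility and expression change.

    ``promoter_atac`` holds one row per promoter OCR with columns gene_id,
    peak_id, log2FC, q and abs_distance (centre-to-TSS); a gene with several
    promoter OCRs is represented by the one with the smallest q (ties:
    largest |log2FC|, then nearest TSS).  ``rna`` is a differential table
    indexed by gene_id with log2FC and q.  Only genes significant on BOTH
    axes receive one of the four quadrants (by the sign pair of the two fold
    changes); the rest carry quadrant "".

    Returns one row per gene with both measurements; ``.attrs['counts']``
    holds the four quadrant counts in the order
    open_up_expr_up, open_up_expr_down, open_down_expr_up, open_down_expr_down.
    """
    req = {"gene_id", "peak_id", "log2FC", "q", "abs_distance"}
    if not req <= set(promoter_atac.columns):
        raise ValueError(f"promoter_atac missing columns {sorted(req - set(promoter_atac.columns))}")
    pa = promoter_atac.copy()
    pa["_abs_lfc"] = pa["log2FC"].abs()
    pa = pa.sort_values(
        ["gene_id", "q", "_abs_lfc", "abs_distance", "peak_id"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("gene_id", keep="first")

    df = pa.merge(
        rna[["log2FC", "q"]].rename(columns={"log2FC": "rna_log2FC", "q": "rna_q"}),
        left_on="gene_id",
        right_index=True,
        how="inner",
    ).rename(columns={"log2FC": "atac_log2FC", "q": "atac_q"})

    atac_sig = (df["atac_log2FC"].abs() >= atac_lfc) & (df["atac_q"] <= q_threshold)
    rna_sig = (df["rna_log2FC"].abs() >= rna_lfc) & (df["rna_q"] <= q_threshold)
    both = atac_sig & rna_sig
    quadrant = np.where(
        both & (df["atac_log2FC"] > 0) & (df["rna_log2FC"] > 0), QUADRANT_LABELS[0],
        np.where(
            both & (df["atac_log2FC"] > 0), QUADRANT_LABELS[1],
            np.where(
                both & (df["rna_log2FC"] > 0), QUADRANT_LABELS[2],
                np.where(both, QUADRANT_LABELS[3], ""),
            ),
        ),
    )
    out = df[
        ["gene_id", "peak_id", "atac_log2FC", "atac_q", "rna_log2FC", "rna_q"]
    ].reset_index(drop=True)
    out["quadrant"] = quadrant
    out.attrs["counts"] = {
        lab: int((out["quadrant"] == lab).sum()) for lab in QUADRANT_LABELS
    }
    return out


def ora_enrichment(
    gene_list,
    gene_sets: dict,
    universe,
    min_size: int = 5,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against gene sets.

    For each set: ``k`` = overlap with the list, ``K`` = set size within the
    universe, ``n`` = list size, ``N`` = universe size; the p-value is the
    one-sided upper tail P(X >= k).  Sets are filtered to
    ``min_size <= K <= max_size``; BH q across the tested sets.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if not genes <= universe:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        K = len(members)
        if not (min_size <= K <= max_size):
            continue
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = stats.false_discovery_control(df["p"], method="bh")
        df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = []
    return df
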