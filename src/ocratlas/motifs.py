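"""PWM motif scanning, motif over-representation, and the TF network.

Scanning is an exhaustive log-odds scan of both strands.  Enrichment is a
presence/absence one-sided Fisher exact test of differential-OCR sequences
against non-differential background sequences — deterministic and exactly
testable, in place of model-based motif enrichment.  The TF "interaction"
network connects enriched TFs by the Jaccard similarity of their target
region sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PFM",
    "PWM",
    "pfm_to_pwm",
    "scan_sequences",
    "motif_enrichment",
    "tf_network",
    "write_network",
]

_ALPHABET = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)  # anything unknown scores like N
for _i, _b in enumerate(_ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class PFM:
    """Position frequency matrix: 4 x L base counts in A,C,G,T row order."""

    matrix_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM must be a 4 x L matrix (rows A,C,G,T)")
        if np.any(self.counts < 0):
            raise ValueError("PFM entries must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("PFM column sums must be positive")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Highest-count base per column (ties: first in A,C,G,T order)."""
        return "".join(_ALPHABET[i] for i in np.argmax(self.counts, axis=0))


@dataclass
class PWM:
    """Log2-odds position weight matrix derived from a PFM."""

    matrix_id: str
    name: str
    matrix: np.ndarray  # 4 x L, bits
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        """Best attainable score: sum of per-column maxima (bits)."""
        return float(self.matrix.max(axis=0).sum())


def pfm_to_pwm(pfm: PFM, background=(0.25, 0.25, 0.25, 0.25), pseudocount: float = 0.8) -> PWM:
    """Convert counts to log2 odds against the background.

    Column probabilities are ``(count + pseudocount) / (colsum + 4*pseudocount)``;
    the PWM entry is ``log2(p / background)``.  With uniform counts and a
    uniform background a column is exactly zero; in the pseudocount -> 0
    limit a one-hot column scores log2(4) = 2 bits for its base.
    """
    bg = np.asarray(background, dtype=float).reshape(4, 1)
    colsum = pfm.counts.sum(axis=0, keepdims=True)
    p = (pfm.counts + pseudocount) / (colsum + 4.0 * pseudocount)
    return PWM(pfm.matrix_id, pfm.name, np.log2(p / bg), bg.ravel())


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of every window; N (code 4) contributes zero."""
    L = matrix.shape[1]
    ext = np.vstack([matrix, np.zeros((1, L))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return ext[windows, np.arange(L)].sum(axis=1)


def scan_sequences(
    pwm: PWM,
    sequences,
    threshold: float | None = None,
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Exhaustively scan both strands of every sequence.

    ``sequences`` maps sequence id -> string (ACGTN; N scores zero).  All
    windows scoring at least the threshold are reported.  ``threshold`` is
    an absolute score in bits; when None, ``threshold_fraction`` of the
    maximum attainable score is used.  Sequences shorter than the motif are
    skipped.  A minus-strand hit at ``offset`` means the motif matches the
    reverse complement of ``seq[offset:offset+L]``; the offset is always in
    forward-strand coordinates.

    Returns a DataFrame with columns seq_id, offset, strand, score, sorted
    by (seq_id, offset, strand).
    """
    if threshold is None:
        threshold = threshold_fraction * pwm.max_score
    L = pwm.length
    # reverse complement scan: complement = reversed ACGT row order,
    # reversed column order
    rc_matrix = pwm.matrix[::-1, ::-1]
    rows = []
    for seq_id, seq in dict(sequences).items():
        if len(seq) < L:
            continue
        codes = _encode(seq)
        for strand, mat in (("+", pwm.matrix), ("-", rc_matrix)):
            scores = _window_scores(codes, mat)
            hit = np.nonzero(scores >= threshold)[0]
            for off in hit:
                rows.append((seq_id, int(off), strand, float(scores[off])))
    df = pd.DataFrame(rows, columns=["seq_id", "offset", "strand", "score"])
    return df.sort_values(["seq_id", "offset", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def motif_enrichment(
    pwms,
    foreground,
    background,
    threshold_fraction: float = 0.8,
    top_k: int = 30,
) -> pd.DataFrame:
    """Rank motifs by over-representation in foreground vs background sequences.

    For each motif: ``a`` = foreground sequences with >= 1 hit, ``b`` =
    background sequences with >= 1 hit; one-sided Fisher exact (greater) on
    the 2x2 presence table; BH q across motifs.  Rows are ranked by
    ascending p (ties: matrix id), with ``rank`` 1-based and ``top`` marking
    the first ``top_k``.  Motifs with no hits anywhere are retained at p=1.
    """
    fg = dict(foreground)
    bg = dict(background)
    if not fg or not bg:
        raise ValueError("need at least one foreground and one background sequence")
    rows = []
    for pwm in pwms:
        if isinstance(pwm, PFM):
            pwm = pfm_to_pwm(pwm)
        a = len(set(scan_sequences(pwm, fg, threshold_fraction=threshold_fraction)["seq_id"]))
        b = len(set(scan_sequences(pwm, bg, threshold_fraction=threshold_fraction)["seq_id"]))
        table = [[a, len(fg) - a], [b, len(bg) - b]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append((pwm.matrix_id, pwm.name, a, len(fg), b, len(bg), odds, p))
    df = pd.DataFrame(
        rows,
        columns=["motif_id", "name", "n_fg_hit", "n_fg", "n_bg_hit", "n_bg", "odds", "p"],
    )
    df["q"] = stats.false_discovery_control(df["p"], method="bh")
    df = df.sort_values(["p", "motif_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["top"] = df["rank"] <= top_k
    return df


def tf_network(
    tf_targets: dict,
    rna_diff: pd.DataFrame | None = None,
    enrichment: pd.DataFrame | None = None,
    top_k: int = 30,
    min_jaccard: float = 0.1,
):
    """Build the TF interaction network from shared target regions.

    ``tf_targets`` maps TF/motif id -> set of target region ids (regions
    with >= 1 hit of that TF's motif).  When an ``enrichment`` table (from
    :func:`motif_enrichment`) is given, only its ``top_k`` best-ranked TFs
    become nodes and their q values annotate the nodes.  Node attribute
    ``rna_log2fc`` is joined from ``rna_diff`` (a DataFrame indexed by gene
    id with a ``log2FC`` column); TFs absent from it get 0 with
    ``rna_missing=True``.  Edges connect TF pairs whose target-set Jaccard
    similarity is >= ``min_jaccard``; weights lie in (0, 1] and there are no
    self edges.

    Returns a ``networkx.Graph``.
    """
    import networkx as nx

    if enrichment is not None:
        keep = [t for t in enrichment.sort_values("rank")["motif_id"][:top_k] if t in tf_targets]
        qmap = dict(zip(enrichment["motif_id"], enrichment["q"]))
    else:
        keep = sorted(tf_targets)[:top_k]
        qmap = {}
    if len(keep) < 2:
        raise ValueError("need at least two enriched TFs to build a network")

    g = nx.Graph()
    for tf in keep:
        lfc, missing = 0.0, True
        if rna_diff is not None and tf in rna_diff.index:
            lfc, missing = float(rna_diff.loc[tf, "log2FC"]), False
        g.add_node(
            tf,
            n_targets=len(tf_targets[tf]),
            enrichment_q=float(qmap.get(tf, np.nan)),
            rna_log2fc=lfc,
            rna_missing=missing,
        )
    for i, ti in enumerate(keep):
        for tj in keep[i + 1 :]:
            si, sj = set(tf_targets[ti]), set(tf_targets[tj])
            union = si | sj
            if not union:
                continue
            jac = len(si & sj) / len(union)
            if jac >= min_jaccard:
                g.add_edge(ti, tj, weight=jac)
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree(n)
    return g


def write_network(graph, edges_path, graphml_path=None) -> None:
    """Write the network as an edge-list TSV (and optionally GraphML XML)."""
    with open(edges_path, "w") as fh:
        fh.write("tf_a\ttf_b\tjaccard\n")
        for a, b, d in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']:.6g}\n")
    if graphml_path is not None:
        import networkx as nx

        nx.write_graphml(graph, graphml_path)
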